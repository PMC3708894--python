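"""End-to-end orchestration: synth -> preprocess -> inverse -> spectral ->
connectivity -> stats, with per-stage persistence and a checksum manifest.

Every stage can be re-run from the artifacts persisted by its upstream
stage, and a re-run from the same configuration reproduces all outputs
bit-identically (fixed seeds everywhere, HDF5 written without
timestamps).  The in-memory :func:`analyze_cohort` path runs the same
computations without the disk round-trips; simulation studies use it
directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import inverse as inv
from . import io as _io
from . import preprocess as pre
from . import spectral as spe
from . import stats as sta
from . import synth as syn
from .montage import ROI_ORDER

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "inverse", "spectral", "connectivity", "stats")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SynthSection:
    n_subjects: int = 21
    duration_s: float = 90.0
    noise_floor: float = 2.0
    n_vertices_per_roi: int = 4
    space_seed: int = 0
    seed_ad: int = 2
    seed_mci: int = 1
    format: str = "edf"
    identical_groups: bool = False   # null-cohort mode: both groups MCI-like


@dataclass
class PreprocessSection:
    filter_order: int = 4
    lo: float = 1.0
    hi: float = 40.0
    ica: bool = True
    n_components: int | None = None
    ica_seed: int = 0
    thresholds: dict = field(default_factory=dict)
    epoch_length_s: float = 2.0
    n_select: int = 30
    epoch_seed: int = 0


@dataclass
class InverseSection:
    lambda2: float = 0.33
    gamma: float = 0.5


@dataclass
class SpectralSection:
    window: str = "hann"
    include_gap: bool = False
    iaf_lo: float = 7.0
    iaf_hi: float = 13.0


@dataclass
class StatsSection:
    alpha: float = 0.05
    q: float = 0.05
    sphericity_correction: bool = True


@dataclass
class RunConfig:
    out_dir: str = "results"
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    inverse: InverseSection = field(default_factory=InverseSection)
    spectral: SpectralSection = field(default_factory=SpectralSection)
    stats: StatsSection = field(default_factory=StatsSection)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sect in (("synth", SynthSection), ("preprocess", PreprocessSection),
                           ("inverse", InverseSection), ("spectral", SpectralSection),
                           ("stats", StatsSection)):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sect(**kw[name])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-subject building blocks (shared by disk stages and in-memory path)

def _preprocess_subject(rec: pre.EEGRecording, p: PreprocessSection,
                        subject_index: int) -> tuple[pre.EpochSet, int]:
    thr = (pre.RejectionThresholds(**p.thresholds) if p.thresholds
           else pre.RejectionThresholds())
    eset, rejected = pre.preprocess_recording(
        rec, lo=p.lo, hi=p.hi, filter_order=p.filter_order,
        epoch_length_s=p.epoch_length_s, n_select=p.n_select, ica=p.ica,
        n_components=p.n_components,
        seed=int(p.ica_seed + 1000 * subject_index + 17), thresholds=thr)
    return eset, len(rejected)


def _spectral_subject(rts: inv.ROITimeSeries, s: SpectralSection,
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    spec = spe.epoch_spectrum(rts, window=s.window)
    iaf = spe.detect_iaf(spec, search_lo=s.iaf_lo, search_hi=s.iaf_hi)
    scheme = spe.BandScheme(iaf=iaf)
    if s.include_gap:
        bp, gap = spe.band_power(spec, scheme, return_gap=True)
        bp_norm = spe.normalize(bp, gap=gap)
    else:
        bp_norm = spe.normalize(spe.band_power(spec, scheme))
    peaks = np.array([spe.peak_frequency(spec, roi) for roi in ROI_ORDER])
    return iaf, bp_norm, peaks


# ---------------------------------------------------------------------------
# in-memory cohort analysis

@dataclass
class CohortResult:
    """All intermediate and final quantities of one cohort analysis."""

    metadata: pd.DataFrame
    activation: np.ndarray          # (S, 12) mean |current|, pAm
    iaf: np.ndarray                 # (S,)
    band_power: spe.BandPowerTable  # normalized, (S, 12, 7)
    peaks: np.ndarray               # (S, 12)
    connectivity: conn.ConnectivityTensor
    n_rejected: np.ndarray          # (S,) rejected ICA components
    report: sta.StatsReport | None = None


def analyze_cohort(cohort: syn.Cohort, space: syn.SourceSpace,
                   lf: syn.LeadField, config: RunConfig | None = None,
                   ) -> CohortResult:
    """Run preprocessing through connectivity for every subject."""
    cfg = config or RunConfig()
    op = inv.build_inverse(lf, lambda2=cfg.inverse.lambda2,
                           gamma=cfg.inverse.gamma)
    n_sub = len(cohort.recordings)
    activation = np.empty((n_sub, len(ROI_ORDER)))
    iafs = np.empty(n_sub)
    bps = np.empty((n_sub, len(ROI_ORDER), len(spe.BAND_ORDER)))
    peaks = np.empty((n_sub, len(ROI_ORDER)))
    ics = np.empty((n_sub, len(conn.PAIR_LABELS), len(spe.BAND_ORDER)))
    zs = np.empty_like(ics)
    n_rej = np.zeros(n_sub, dtype=int)
    for s, rec in enumerate(cohort.recordings):
        eset, n_rej[s] = _preprocess_subject(rec, cfg.preprocess, s)
        currents = inv.apply_inverse(op, eset)
        rts = inv.extract_roi(currents, space, fs=eset.fs)
        activation[s] = inv.mean_activation(rts)
        iafs[s], bps[s], peaks[s] = _spectral_subject(rts, cfg.spectral)
        ics[s], zs[s] = conn.subject_connectivity(
            rts, spe.BandScheme(iaf=iafs[s]), window=cfg.spectral.window)
    meta = cohort.metadata
    bpt = spe.BandPowerTable(values=bps, subjects=list(meta["subject_id"]),
                             groups=list(meta["group"]), iaf=iafs)
    ct = conn.ConnectivityTensor(ic=ics, z=zs,
                                 subjects=list(meta["subject_id"]),
                                 groups=list(meta["group"]))
    return CohortResult(metadata=meta, activation=activation, iaf=iafs,
                        band_power=bpt, peaks=peaks, connectivity=ct,
                        n_rejected=n_rej)


def run_stats(result: CohortResult, config: RunConfig | None = None,
              ) -> sta.StatsReport:
    """The full statistical battery on an analyzed cohort."""
    cfg = config or RunConfig()
    meta = result.metadata
    groups = np.asarray(meta["group"])
    names = list(dict.fromkeys(groups))
    if len(names) != 2:
        raise ValueError("stats stage needs exactly two groups")
    for gname in names:
        if int((groups == gname).sum()) < 2:
            raise ValueError(
                f"stats stage needs >= 2 subjects per group; group "
                f"{gname!r} has {(groups == gname).sum()}")
    corr = cfg.stats.sphericity_correction

    act = pd.DataFrame({
        "subject": np.repeat(meta["subject_id"], len(ROI_ORDER)),
        "group": np.repeat(groups, len(ROI_ORDER)),
        "roi": np.tile(ROI_ORDER, len(meta)),
        "value": result.activation.ravel()})
    aov_act = sta.anova_activation(act, correction=corr)

    tidy_bp = result.band_power.to_tidy()
    aov_pow = sta.anova_power(tidy_bp, correction=corr)
    posthoc = {"band": sta.pairwise_bonferroni(tidy_bp, factor="band"),
               "roi": sta.pairwise_bonferroni(tidy_bp, factor="roi")}

    mask_a = groups == names[0]
    contrasts = sta.connectivity_contrasts(
        result.connectivity.z[mask_a], result.connectivity.z[~mask_a],
        group_names=(names[0], names[1]), q=cfg.stats.q)

    mmse = np.asarray(meta["mmse"], dtype=float)
    pow_corr = sta.power_mmse_correlations(result.band_power.values, mmse)
    con_corr = sta.connectivity_mmse_correlations(result.connectivity.z, mmse)
    return sta.StatsReport(anova_activation=aov_act, anova_power=aov_pow,
                           posthoc=posthoc, connectivity_contrasts=contrasts,
                           power_correlations=pow_corr,
                           connectivity_correlations=con_corr)


# ---------------------------------------------------------------------------
# disk-backed stages

def _h5_write(path: Path, arrays: dict[str, np.ndarray],
              attrs: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        for k, v in arrays.items():
            fh.create_dataset(k, data=v, track_times=False)
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def _h5_read(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as fh:
        arrays = {k: fh[k][()] for k in fh.keys()}
        attrs = dict(fh.attrs)
    return arrays, attrs


def _specs_from_config(cfg: RunConfig) -> tuple[syn.CohortSpec, syn.CohortSpec]:
    s = cfg.synth
    common = dict(n_subjects=s.n_subjects, duration_s=s.duration_s,
                  noise_floor=s.noise_floor)
    spec_mci = syn.mci_like_spec(seed=s.seed_mci, **common)
    if s.identical_groups:
        spec_ad = syn.mci_like_spec(group_name="AD", seed=s.seed_ad, **common)
    else:
        spec_ad = syn.ad_like_spec(seed=s.seed_ad, **common)
    return spec_ad, spec_mci


def _geometry(cfg: RunConfig) -> tuple[syn.SourceSpace, syn.LeadField]:
    space = syn.make_source_space(cfg.synth.n_vertices_per_roi,
                                  seed=cfg.synth.space_seed)
    return space, syn.make_lead_field(space)


def run_synth(cfg: RunConfig) -> Path:
    """Generate and persist the synthetic cohort (recordings + metadata +
    ground truth); returns the cohort directory."""
    if cfg.synth.n_subjects < 2:
        raise ValueError("n_subjects per group must be >= 2")
    out = Path(cfg.out_dir)
    cohort_dir = out / "cohort"
    spec_ad, spec_mci = _specs_from_config(cfg)
    space, lf = _geometry(cfg)
    cohort = syn.make_cohort(spec_ad, spec_mci, space, lf)
    cohort.save(cohort_dir, fmt=cfg.synth.format)
    _h5_write(out / "leadfield.h5",
              {"gain": lf.matrix, "mastoid_gain": lf.mastoid_matrix,
               "vertex_positions": space.vertex_positions,
               "vertex_normals": space.vertex_normals},
              {"roi_labels": [str(r) for r in space.roi_labels],
               "condition_number": lf.condition_number})
    return cohort_dir


def _load_geometry(out: Path) -> tuple[syn.SourceSpace, syn.LeadField]:
    arrays, attrs = _h5_read(out / "leadfield.h5")
    space = syn.SourceSpace(vertex_positions=arrays["vertex_positions"],
                            vertex_normals=arrays["vertex_normals"],
                            roi_labels=np.asarray(attrs["roi_labels"]))
    lf = syn.LeadField(matrix=arrays["gain"],
                       mastoid_matrix=arrays["mastoid_gain"],
                       condition_number=float(attrs["condition_number"]))
    return space, lf


def stage_preprocess(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    meta = _io.read_metadata(out / "cohort" / "metadata.csv")
    epochs, n_rej = [], []
    fs = 200.0
    for s, sid in enumerate(meta["subject_id"]):
        path = out / "cohort" / f"{sid}.{cfg.synth.format}"
        rec = pre.read_recording(path, units="uV")
        fs = rec.fs
        eset, nr = _preprocess_subject(rec, cfg.preprocess, s)
        epochs.append(eset.epochs)
        n_rej.append(nr)
    _h5_write(out / "epochs.h5", {"epochs": np.asarray(epochs)},
              {"fs": fs, "n_rejected": n_rej})
    return out / "epochs.h5"


def stage_inverse(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    space, lf = _load_geometry(out)
    arrays, attrs = _h5_read(out / "epochs.h5")
    fs = float(attrs["fs"])
    op = inv.build_inverse(lf, lambda2=cfg.inverse.lambda2,
                           gamma=cfg.inverse.gamma)
    roi_courses, activation = [], []
    for ep in arrays["epochs"]:
        eset = pre.EpochSet(epochs=ep, fs=fs)
        rts = inv.extract_roi(inv.apply_inverse(op, eset), space, fs=fs)
        roi_courses.append(rts.data)
        activation.append(inv.mean_activation(rts))
    _h5_write(out / "roi_currents.h5",
              {"currents": np.asarray(roi_courses)}, {"fs": fs})
    meta = _io.read_metadata(out / "cohort" / "metadata.csv")
    act = pd.DataFrame(np.asarray(activation), columns=ROI_ORDER)
    act.insert(0, "subject", meta["subject_id"])
    act.insert(1, "group", meta["group"])
    act.to_csv(out / "activation.csv", index=False)
    return out / "roi_currents.h5"


def stage_spectral(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    arrays, attrs = _h5_read(out / "roi_currents.h5")
    fs = float(attrs["fs"])
    meta = _io.read_metadata(out / "cohort" / "metadata.csv")
    rows, iafs, peak_rows, spectra = [], [], [], []
    freqs = None
    for s, sid in enumerate(meta["subject_id"]):
        rts = inv.ROITimeSeries(data=arrays["currents"][s], fs=fs)
        spectrum = spe.epoch_spectrum(rts, window=cfg.spectral.window)
        spectra.append(spectrum.power)
        freqs = spectrum.freqs
        iaf, bp_norm, peaks = _spectral_subject(rts, cfg.spectral)
        iafs.append({"subject": sid, "group": meta["group"].iloc[s], "iaf": iaf})
        for r, roi in enumerate(ROI_ORDER):
            peak_rows.append({"subject": sid, "roi": roi,
                              "peak_hz": peaks[r]})
            for b, band in enumerate(spe.BAND_ORDER):
                rows.append({"subject": sid, "group": meta["group"].iloc[s],
                             "roi": roi, "band": band,
                             "value": bp_norm[r, b]})
    pd.DataFrame(rows).to_csv(out / "band_power.csv", index=False)
    pd.DataFrame(iafs).to_csv(out / "iaf.csv", index=False)
    pd.DataFrame(peak_rows).to_csv(out / "peak_frequency.csv", index=False)
    _h5_write(out / "spectra.h5", {"power": np.asarray(spectra),
                                   "freqs": freqs}, {"fs": fs})
    return out / "band_power.csv"


def stage_connectivity(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    arrays, attrs = _h5_read(out / "roi_currents.h5")
    fs = float(attrs["fs"])
    meta = _io.read_metadata(out / "cohort" / "metadata.csv")
    iaf = _io.read_metadata(out / "iaf.csv")
    rows, ics, zs = [], [], []
    for s, sid in enumerate(meta["subject_id"]):
        rts = inv.ROITimeSeries(data=arrays["currents"][s], fs=fs)
        scheme = spe.BandScheme(iaf=float(iaf["iaf"].iloc[s]))
        bic, z = conn.subject_connectivity(rts, scheme,
                                           window=cfg.spectral.window)
        ics.append(bic)
        zs.append(z)
        for p, pair in enumerate(conn.PAIR_LABELS):
            for b, band in enumerate(spe.BAND_ORDER):
                rows.append({"subject": sid, "group": meta["group"].iloc[s],
                             "pair": pair, "band": band,
                             "ic": bic[p, b], "z": z[p, b]})
    pd.DataFrame(rows).to_csv(out / "connectivity.csv", index=False)
    _h5_write(out / "connectivity.h5",
              {"ic": np.asarray(ics), "z": np.asarray(zs)}, {"fs": fs})
    return out / "connectivity.csv"


def stage_stats(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    meta = _io.read_metadata(out / "cohort" / "metadata.csv")
    groups = np.asarray(meta["group"])
    names = list(dict.fromkeys(groups))
    if len(names) != 2 or min((groups == n).sum() for n in names) < 2:
        raise ValueError("stats stage needs two groups with >= 2 subjects each")
    corr = cfg.stats.sphericity_correction

    act = pd.read_csv(out / "activation.csv").melt(
        id_vars=["subject", "group"], var_name="roi", value_name="value")
    sta.anova_activation(act, correction=corr).to_csv(
        out / "anova_activation.csv", index=False)

    bp = pd.read_csv(out / "band_power.csv")
    sta.anova_power(bp, correction=corr).to_csv(out / "anova_power.csv",
                                                index=False)
    sta.pairwise_bonferroni(bp, factor="band").to_csv(
        out / "posthoc_band.csv", index=False)

    cz = pd.read_csv(out / "connectivity.csv")
    n_pairs, n_bands = len(conn.PAIR_LABELS), len(spe.BAND_ORDER)

    def z_tensor(gname: str) -> np.ndarray:
        sub = cz[cz["group"] == gname]
        piv = sub.pivot_table(index="subject", columns=["pair", "band"],
                              values="z", sort=False)
        cols = pd.MultiIndex.from_product([conn.PAIR_LABELS, spe.BAND_ORDER])
        return piv[cols].to_numpy().reshape(-1, n_pairs, n_bands)

    contrasts = sta.connectivity_contrasts(
        z_tensor(names[0]), z_tensor(names[1]),
        group_names=(str(names[0]), str(names[1])), q=cfg.stats.q)
    contrasts.to_csv(out / "connectivity_contrasts.csv", index=False)

    mmse = np.asarray(meta["mmse"], dtype=float)
    piv_bp = bp.pivot_table(index="subject", columns=["roi", "band"],
                            values="value", sort=False)
    order = pd.MultiIndex.from_product([ROI_ORDER, spe.BAND_ORDER])
    sid_order = list(meta["subject_id"])
    values = piv_bp.loc[sid_order, order].to_numpy().reshape(
        -1, len(ROI_ORDER), n_bands)
    sta.power_mmse_correlations(values, mmse).to_csv(
        out / "power_correlations.csv", index=False)
    piv_z = cz.pivot_table(index="subject", columns=["pair", "band"],
                           values="z", sort=False)
    zcols = pd.MultiIndex.from_product([conn.PAIR_LABELS, spe.BAND_ORDER])
    zvals = piv_z.loc[sid_order, zcols].to_numpy().reshape(
        -1, n_pairs, n_bands)
    sta.connectivity_mmse_correlations(zvals, mmse).to_csv(
        out / "connectivity_correlations.csv", index=False)
    return out / "connectivity_contrasts.csv"


_STAGE_FUNCS = {"preprocess": stage_preprocess, "inverse": stage_inverse,
                "spectral": stage_spectral, "connectivity": stage_connectivity,
                "stats": stage_stats}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path) -> Path:
    """Checksum every persisted artifact in the run directory."""
    out = Path(out_dir)
    entries = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(out))] = _sha256(p)
    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
    return manifest


def run_analysis(cfg: RunConfig, synth_first: bool = True) -> Path:
    """Execute all stages in order; persist config, log and manifest.

    Any stage failure raises :class:`StageError` naming the stage;
    artifacts written before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    if synth_first:
        t0 = time.perf_counter()
        try:
            run_synth(cfg)
        except Exception as err:
            raise StageError("synth", err) from err
        logger.info("stage synth: %.1f s", time.perf_counter() - t0)
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as err:
            raise StageError(stage, err) from err
        logger.info("stage %s: %.1f s", stage, time.perf_counter() - t0)
    return write_manifest(out)
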
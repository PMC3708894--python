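"""Synthetic resting-state EEG cohorts with known ground truth.

The generator emulates eyes-closed resting EEG from two clinical-like
groups.  Each subject's 12 DMN region sources are built as a 1/f
background plus narrowband stochastic oscillators (AR(2) processes whose
delta/theta/alpha centre frequencies track the subject's individual alpha
frequency), optionally phase-lagged coupling between selected ROI pairs,
forward-projected through the three-shell spherical head model to the 19
sensors of the 10-20 montage, with i.i.d. sensor noise on top.  Ocular
and muscle artifact components can be injected afterwards with their
insertion times recorded for test assertions.

Group profiles follow the disease contrast under study: relative to the
MCI-like group, the AD-like group has attenuated alpha/beta and enhanced
delta/theta oscillator amplitudes in the posterior DMN regions (medial
temporal, inferior parietal, posterior cingulate, precuneus), a slightly
lower mean individual alpha frequency (8.7 vs 9.1 Hz), and a lower
synthetic MMSE score (14.9 +/- 5.4 vs 22.7 +/- 2.2) whose subject-level
residual is linked to posterior alpha amplitude by a configurable slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import io as _io
from .headmodel import GeometryError, ThreeShellModel
from .montage import (CHANNELS_1020, MASTOIDS, POSTERIOR_ROIS, ROI_ORDER,
                      electrode_positions, roi_centroid)
from .preprocess import EEGRecording

logger = logging.getLogger(__name__)

OSC_BANDS = ("delta", "theta", "alpha", "beta", "gamma")
_POSTERIOR_BASES = ("MT", "IPC", "PCC", "PCu")


@dataclass
class SourceSpace:
    """Toy cortical source space: jittered vertices around 12 canonical
    DMN centroids, with outward (radial) orientations."""

    vertex_positions: np.ndarray   # (V, 3) metres
    vertex_normals: np.ndarray     # (V, 3) unit vectors
    roi_labels: np.ndarray         # (V,) strings from ROI_ORDER

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex normals must have unit length")
        for roi in ROI_ORDER:
            if not np.any(self.roi_labels == roi):
                raise ValueError(f"ROI {roi} has no vertices")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    def roi_indices(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == roi)


@dataclass
class LeadField:
    """Fixed-orientation gain matrix, microvolts per picoampere-metre."""

    matrix: np.ndarray             # (19, V)
    sensor_labels: tuple[str, ...] = CHANNELS_1020
    mastoid_matrix: np.ndarray | None = None   # (2, V) gains at A1/A2
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.sensor_labels):
            raise ValueError("gain rows must match sensor labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("gain matrix must be finite")


@dataclass(frozen=True)
class CouplingEdge:
    """A lagged linear coupling between two ROIs.

    The shared oscillator at ``freq_hz`` is added to both regions, the
    second lagging the first by ``lag_rad`` radians at the centre
    frequency; ``strength`` in [0, 1] scales the coupling amplitude.
    """

    roi_a: str
    roi_b: str
    freq_hz: float
    lag_rad: float
    strength: float

    def __post_init__(self) -> None:
        if not (-np.pi < self.lag_rad <= np.pi):
            raise ValueError("lag must lie in (-pi, pi]")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic group."""

    group_name: str
    n_subjects: int = 21
    iaf_mean: float = 9.1           # Hz
    iaf_sd: float = 0.7             # Hz
    band_profiles: dict = field(default_factory=dict)   # roi -> band -> RMS pAm
    background_amplitude: float = 4e4                    # 1/f RMS, pAm
    coupling_edges: list[CouplingEdge] = field(default_factory=list)
    coupling_amplitude: float = 4e4                      # RMS pAm at strength 1
    noise_floor: float = 2.0        # sensor noise SD, microvolts
    mmse_mean: float = 22.7
    mmse_sd: float = 2.2
    mmse_alpha_slope: float = 2.0   # MMSE points per SD of posterior alpha
    amplitude_jitter_sd: float = 0.15   # log-normal sigma, per subject/ROI/band
    pole_radius: float = 0.96       # AR(2) oscillator bandwidth parameter
    pure_sinusoid: bool = False     # analytic-test mode
    duration_s: float = 90.0
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_floor < 0 or self.background_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        for roi, prof in self.band_profiles.items():
            if roi not in ROI_ORDER:
                raise ValueError(f"unknown ROI in profile: {roi}")
            for band, amp in prof.items():
                if band not in OSC_BANDS:
                    raise ValueError(f"unknown oscillator band: {band}")
                if amp < 0:
                    raise ValueError("oscillator amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Generating parameters of one subject, stored with every cohort."""

    subject_id: str
    group: str
    iaf: float
    band_amplitudes: dict           # roi -> band -> RMS pAm (post-jitter)
    edges: list[dict]
    mmse: int | None = None

    def to_dict(self) -> dict:
        return {"subject_id": self.subject_id, "group": self.group,
                "iaf": self.iaf, "band_amplitudes": self.band_amplitudes,
                "edges": self.edges, "mmse": self.mmse}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# default group profiles (the study conditions)

_BASE_ANTERIOR = {"delta": 3.0e4, "theta": 4.0e4, "alpha": 6.0e4,
                  "beta": 2.5e4, "gamma": 8.0e3}
_BASE_POSTERIOR = {"delta": 3.0e4, "theta": 4.0e4, "alpha": 1.2e5,
                   "beta": 3.0e4, "gamma": 8.0e3}
#: AD-like multiplicative changes applied to posterior ROIs only.
AD_POSTERIOR_FACTORS = {"delta": 1.3, "theta": 1.4, "alpha": 0.7, "beta": 0.8,
                        "gamma": 1.0}


def default_band_profiles(posterior_factors: dict[str, float] | None = None) -> dict:
    """Per-ROI oscillator amplitude profile; optional posterior scaling."""
    prof = {}
    for roi in ROI_ORDER:
        base = roi.rsplit("_", 1)[0]
        if base in _POSTERIOR_BASES:
            amps = dict(_BASE_POSTERIOR)
            if posterior_factors:
                amps = {b: a * posterior_factors.get(b, 1.0)
                        for b, a in amps.items()}
        else:
            amps = dict(_BASE_ANTERIOR)
        prof[roi] = amps
    return prof


def _default_edges_mci() -> list[CouplingEdge]:
    return [CouplingEdge("PCC_L", "PCu_L", 10.0, np.pi / 2, 0.5),
            CouplingEdge("PCC_R", "PCu_R", 10.0, np.pi / 2, 0.5)]


def _default_edges_ad() -> list[CouplingEdge]:
    return [CouplingEdge("PCC_L", "PCu_L", 10.0, np.pi / 2, 0.2),
            CouplingEdge("PCC_R", "PCu_R", 10.0, np.pi / 2, 0.2),
            CouplingEdge("MFC_R", "MT_R", 2.5, np.pi / 2, 0.4),
            CouplingEdge("MT_R", "PCC_R", 5.5, np.pi / 2, 0.4)]


def mci_like_spec(**overrides) -> CohortSpec:
    """Default MCI-like group: IAF 9.1 +/- 0.7 Hz, MMSE 22.7 +/- 2.2."""
    kw = dict(group_name="MCI", iaf_mean=9.1, iaf_sd=0.7,
              band_profiles=default_band_profiles(),
              coupling_edges=_default_edges_mci(),
              mmse_mean=22.7, mmse_sd=2.2, seed=1)
    kw.update(overrides)
    return CohortSpec(**kw)


def ad_like_spec(**overrides) -> CohortSpec:
    """Default AD-like group: posterior alpha/beta attenuated, delta/theta
    enhanced; IAF 8.7 +/- 0.6 Hz; MMSE 14.9 +/- 5.4."""
    kw = dict(group_name="AD", iaf_mean=8.7, iaf_sd=0.6,
              band_profiles=default_band_profiles(AD_POSTERIOR_FACTORS),
              coupling_edges=_default_edges_ad(),
              mmse_mean=14.9, mmse_sd=5.4, seed=2)
    kw.update(overrides)
    return CohortSpec(**kw)


# ---------------------------------------------------------------------------
# geometry and forward model

def make_source_space(n_vertices_per_roi: int = 1, seed: int = 0,
                      spread: float = 0.003) -> SourceSpace:
    """Scatter vertices around the canonical ROI centroids.

    The first vertex of every ROI sits exactly on the centroid, so a
    one-vertex-per-ROI space is bilaterally mirrored by construction.
    Patches are kept compact (3 mm scatter by default) so that, with only
    19 sensors, neighbouring medial regions remain separable; all
    vertices stay strictly inside the inner (brain) shell.
    """
    if n_vertices_per_roi < 1:
        raise ValueError("n_vertices_per_roi must be >= 1")
    rng = np.random.default_rng(seed)
    max_r = 0.085
    positions, labels = [], []
    for roi in ROI_ORDER:
        c = roi_centroid(roi)
        for k in range(n_vertices_per_roi):
            p = c if k == 0 else c + rng.normal(0.0, spread, 3)
            r = np.linalg.norm(p)
            if r > max_r:
                p = p * (max_r / r)
            positions.append(p)
            labels.append(roi)
    positions = np.asarray(positions)
    normals = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    return SourceSpace(vertex_positions=positions, vertex_normals=normals,
                       roi_labels=np.asarray(labels))


def make_lead_field(space: SourceSpace,
                    model: ThreeShellModel | None = None) -> LeadField:
    """Analytic spherical-model gain matrix with normal-constrained
    orientations, in microvolts per picoampere-metre."""
    if model is None:
        model = ThreeShellModel()
    for p in space.vertex_positions:
        if np.linalg.norm(p) >= model.inner_radius:
            raise GeometryError("source space vertex outside the inner shell")
    sens = electrode_positions(model.outer_radius, CHANNELS_1020)
    mast = electrode_positions(model.outer_radius, MASTOIDS)
    gain = np.empty((len(CHANNELS_1020), space.n_vertices))
    mgain = np.empty((len(MASTOIDS), space.n_vertices))
    for v in range(space.n_vertices):
        # unit dipole of 1 pAm = 1e-12 Am along the vertex normal; volts->uV
        volts = model.potential(space.vertex_positions[v],
                                space.vertex_normals[v], sens)
        gain[:, v] = volts * 1e-6
        mgain[:, v] = model.potential(space.vertex_positions[v],
                                      space.vertex_normals[v], mast) * 1e-6
    cond = float(np.linalg.cond(gain))
    logger.info("lead field: %d sensors x %d vertices, condition number %.3g",
                gain.shape[0], gain.shape[1], cond)
    return LeadField(matrix=gain, mastoid_matrix=mgain, condition_number=cond)


def roi_gain(space: SourceSpace, lf: LeadField) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the vertex gain matrix to per-ROI columns.

    A ROI source of total moment m(t) is split equally over its member
    vertices, so the effective sensor gain is the vertex-column mean.
    Returns (19 x 12, 2 x 12) for scalp and mastoid sensors.
    """
    g = np.empty((lf.matrix.shape[0], len(ROI_ORDER)))
    gm = np.empty((lf.mastoid_matrix.shape[0], len(ROI_ORDER)))
    for i, roi in enumerate(ROI_ORDER):
        idx = space.roi_indices(roi)
        g[:, i] = lf.matrix[:, idx].mean(axis=1)
        gm[:, i] = lf.mastoid_matrix[:, idx].mean(axis=1)
    return g, gm


# ---------------------------------------------------------------------------
# signal primitives

def _ar2_oscillator(rng: np.random.Generator, f0: float, n: int, fs: float,
                    pole_radius: float) -> np.ndarray:
    """Unit-RMS narrowband AR(2) process centred at f0."""
    a1 = 2 * pole_radius * np.cos(2 * np.pi * f0 / fs)
    a2 = -pole_radius ** 2
    burn = 400
    w = rng.standard_normal(n + burn)
    x = signal.lfilter([1.0], [1.0, -a1, -a2], w)[burn:]
    s = x.std()
    return x / s if s > 0 else x


def _sinusoid(rng: np.random.Generator, f0: float, n: int, fs: float,
              phase: float | None = None) -> np.ndarray:
    """Unit-RMS sinusoid with random (or given) initial phase."""
    if phase is None:
        phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return np.sqrt(2.0) * np.cos(2 * np.pi * f0 * t + phase)


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f noise (spectrum flattened below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x / s if s > 0 else x


def _lagged_copy(s: np.ndarray, lag_rad: float) -> np.ndarray:
    """Phase-lagged copy of a narrowband signal via analytic-signal rotation."""
    return np.real(signal.hilbert(s) * np.exp(-1j * lag_rad))


# ---------------------------------------------------------------------------
# subject and cohort synthesis

def _band_centers(iaf: float) -> dict[str, float]:
    # delta/theta/alpha oscillators track the IAF; beta/gamma are fixed
    return {"delta": iaf - 7.0, "theta": iaf - 4.0, "alpha": iaf,
            "beta": 16.5, "gamma": 35.0}


def simulate_subject(spec: CohortSpec, space: SourceSpace, lf: LeadField,
                     subject_index: int) -> tuple[EEGRecording, GroundTruth]:
    """Generate one subject's recording and its ground-truth parameters."""
    n = int(round(spec.duration_s * spec.fs))
    epoch_n = int(round(2.0 * spec.fs))
    if n // epoch_n < 30:
        raise ValueError(
            f"duration {spec.duration_s} s yields only {n // epoch_n} 2-s "
            "epochs; at least 30 are required")
    rng = np.random.default_rng([spec.seed, subject_index])
    iaf = float(np.clip(rng.normal(spec.iaf_mean, spec.iaf_sd), 7.2, 12.8))
    centers = _band_centers(iaf)

    def osc(f0: float) -> np.ndarray:
        if spec.pure_sinusoid:
            return _sinusoid(rng, f0, n, spec.fs)
        return _ar2_oscillator(rng, f0, n, spec.fs, spec.pole_radius)

    sources = np.zeros((len(ROI_ORDER), n))
    band_amplitudes: dict[str, dict[str, float]] = {}
    for i, roi in enumerate(ROI_ORDER):
        prof = spec.band_profiles.get(roi, {})
        amps = {}
        for band in OSC_BANDS:
            base = prof.get(band, 0.0)
            amp = base * float(np.exp(rng.normal(0.0, spec.amplitude_jitter_sd)))
            amps[band] = amp
            if amp > 0:
                sources[i] += amp * osc(centers[band])
        band_amplitudes[roi] = amps
        if spec.background_amplitude > 0:
            sources[i] += spec.background_amplitude * _pink_noise(rng, n, spec.fs)

    edges_gt = []
    roi_index = {roi: i for i, roi in enumerate(ROI_ORDER)}
    for edge in spec.coupling_edges:
        amp = spec.coupling_amplitude * edge.strength
        if amp > 0:
            s = osc(edge.freq_hz)
            sources[roi_index[edge.roi_a]] += amp * s
            sources[roi_index[edge.roi_b]] += amp * _lagged_copy(s, edge.lag_rad)
        edges_gt.append({"roi_a": edge.roi_a, "roi_b": edge.roi_b,
                         "freq_hz": edge.freq_hz, "lag_rad": edge.lag_rad,
                         "strength": edge.strength, "amplitude": amp})

    g, gm = roi_gain(space, lf)
    data = g @ sources
    mastoid = gm @ sources
    if spec.noise_floor > 0:
        data = data + rng.normal(0.0, spec.noise_floor, data.shape)
        mastoid = mastoid + rng.normal(0.0, spec.noise_floor, mastoid.shape)

    rec = EEGRecording(data=data, fs=spec.fs, mastoid=mastoid)
    gt = GroundTruth(subject_id=f"{spec.group_name}_{subject_index:02d}",
                     group=spec.group_name, iaf=iaf,
                     band_amplitudes=band_amplitudes, edges=edges_gt)
    return rec, gt


def inject_artifacts(rec: EEGRecording, kinds: set[str], seed: int = 0, *,
                     ocular_amplitude: float = 120.0, ocular_rate_per_min: float = 8.0,
                     muscle_amplitude: float = 20.0, muscle_channel: str = "T3",
                     n_muscle_bursts: int = 6) -> EEGRecording:
    """Add ocular and/or muscle artifact components to a recording.

    Ocular events are slow frontal transients whose topography is maximal
    at Fp1/Fp2 and decays monotonically toward posterior sensors; muscle
    events are focal 20-50 Hz bursts on ``muscle_channel``.  Event onsets
    are appended to ``rec.artifacts``.  An empty ``kinds`` set returns the
    input unchanged.
    """
    unknown = set(kinds) - {"ocular", "muscle"}
    if unknown:
        raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
    if not kinds:
        return rec
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    events = list(rec.artifacts)
    fs = rec.fs
    n = rec.n_samples
    t = np.arange(n) / fs
    pos = electrode_positions(labels=rec.channel_labels)
    y = pos[:, 1]

    if "ocular" in kinds:
        topo = np.exp(-(y.max() - y) / 0.045)   # 1 at Fp1/Fp2, decays backward
        n_events = max(1, int(round(ocular_rate_per_min * rec.duration_s / 60.0)))
        times = np.sort(rng.uniform(1.0, rec.duration_s - 1.0, n_events))
        wave = np.zeros(n)
        for t0 in times:
            wave += np.exp(-0.5 * ((t - t0) / 0.08) ** 2)
            events.append({"kind": "ocular", "time": float(t0),
                           "duration": 0.4, "channel": "Fp1"})
        data += ocular_amplitude * topo[:, None] * wave[None, :]

    if "muscle" in kinds:
        ch = rec.channel_labels.index(muscle_channel)
        d = np.linalg.norm(pos - pos[ch], axis=1)
        topo = np.exp(-d / 0.02)                # focal around the target
        hi = min(50.0, 0.95 * fs / 2)
        sos = signal.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        for _ in range(n_muscle_bursts):
            dur = rng.uniform(0.5, 1.0)
            t0 = rng.uniform(1.0, rec.duration_s - 1.0 - dur)
            i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
            burst = signal.sosfiltfilt(sos, rng.standard_normal(i1 - i0 + 200))[100:-100]
            burst *= signal.windows.tukey(len(burst), 0.25)
            rms = np.sqrt(np.mean(burst ** 2))
            if rms > 0:
                burst *= muscle_amplitude / rms
            data[:, i0:i1] += topo[:, None] * burst[None, :]
            events.append({"kind": "muscle", "time": float(t0),
                           "duration": float(dur), "channel": muscle_channel})

    return replace(rec, data=data, artifacts=events)


@dataclass
class Cohort:
    """A generated two-group cohort bundle."""

    recordings: list[EEGRecording]
    metadata: pd.DataFrame          # subject_id, group, mmse, seed
    ground_truth: list[GroundTruth]

    def save(self, out_dir: str | Path, fmt: str = "edf") -> list[Path]:
        """Write recordings (EDF or CSV, with A1/A2 rows), metadata and
        ground truth to a directory; returns the recording paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for rec, gt in zip(self.recordings, self.ground_truth):
            labels = list(rec.channel_labels) + list(MASTOIDS)
            data = np.vstack([rec.data, rec.mastoid])
            p = out_dir / f"{gt.subject_id}.{fmt}"
            if fmt == "edf":
                _io.write_edf(p, data, labels, rec.fs)
            elif fmt == "csv":
                _io.write_csv(p, data, labels, rec.fs)
            else:
                raise ValueError(f"unknown format {fmt!r}")
            paths.append(p)
        _io.write_metadata(out_dir / "metadata.csv", self.metadata)
        _io.write_ground_truth(out_dir / "ground_truth.json",
                               [gt.to_dict() for gt in self.ground_truth])
        return paths


def _subject_mmse(spec: CohortSpec, gt: GroundTruth, subject_index: int) -> int:
    """Synthetic MMSE: group Gaussian plus an alpha-linked component.

    The subject's posterior-alpha log deviation from the group profile
    (in units of the jitter SD) is multiplied by ``mmse_alpha_slope``, so
    a zero slope decouples MMSE from power by construction.
    """
    rng = np.random.default_rng([spec.seed, subject_index, 7])
    base = rng.normal(spec.mmse_mean, spec.mmse_sd)
    if spec.mmse_alpha_slope != 0.0 and spec.amplitude_jitter_sd > 0:
        zs = []
        for roi in POSTERIOR_ROIS:
            prof = spec.band_profiles.get(roi, {}).get("alpha", 0.0)
            amp = gt.band_amplitudes[roi]["alpha"]
            if prof > 0 and amp > 0:
                zs.append(np.log(amp / prof) / spec.amplitude_jitter_sd)
        if zs:
            base += spec.mmse_alpha_slope * float(np.mean(zs))
    return int(np.clip(round(base), 0, 30))


def make_cohort(spec_a: CohortSpec, spec_b: CohortSpec, space: SourceSpace,
                lf: LeadField) -> Cohort:
    """Generate the full two-group cohort (recordings, metadata, truth)."""
    recordings, gts, rows = [], [], []
    for spec in (spec_a, spec_b):
        for i in range(spec.n_subjects):
            rec, gt = simulate_subject(spec, space, lf, i)
            gt.mmse = _subject_mmse(spec, gt, i)
            recordings.append(rec)
            gts.append(gt)
            rows.append({"subject_id": gt.subject_id, "group": gt.group,
                         "mmse": gt.mmse, "seed": spec.seed})
    return Cohort(recordings=recordings, metadata=pd.DataFrame(rows),
                  ground_truth=gts)
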
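"""Replicated simulation studies: localization accuracy, parameter
recovery, detection power and false-discovery calibration.

These studies run the actual analysis pipeline on freshly generated
synthetic cohorts and summarize how well it recovers what the generator
injected.  Replicate loops use reduced problem sizes (62-s recordings,
one vertex per ROI, ICA stage skipped since no artifacts are injected)
so that hundred-replicate studies stay cheap; the group sizes (21 per
group) and group profiles are the study conditions and are not reduced.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import inverse as inv
from . import preprocess as pre
from . import spectral as spe
from . import synth
from .montage import ROI_ORDER
from .pipeline import SpectralSection, _spectral_subject
from .stats import fdr_bh

#: ROIs carrying the AD-like posterior profile change.
PROFILE_ROIS = tuple(r for r in ROI_ORDER
                     if r.rsplit("_", 1)[0] in ("MT", "IPC", "PCC", "PCu"))


def localization_study(n_fixtures: int = 100, snr: float = 10.0,
                       seed: int = 0, n_vertices_per_roi: int = 6,
                       lambda2: float = 0.33, gamma: float = 0.5) -> float:
    """Single-dipole localization: fraction of random fixtures whose
    maximum-|current| vertex falls in the true ROI.

    Each fixture activates one random vertex with a 10 Hz source, projects
    it to the sensors, adds white noise at the given amplitude SNR, and
    applies the depth-weighted minimum-norm operator.
    """
    rng = np.random.default_rng(seed)
    space = synth.make_source_space(n_vertices_per_roi, seed=seed)
    lf = synth.make_lead_field(space)
    op = inv.build_inverse(lf, lambda2=lambda2, gamma=gamma)
    s = 1e5 * np.sin(2 * np.pi * 10.0 * np.arange(400) / 200.0)
    hits = 0
    for _ in range(n_fixtures):
        v = int(rng.integers(space.n_vertices))
        sens = lf.matrix[:, v][:, None] * s[None, :]
        sens = sens + rng.normal(0.0, sens.std() / snr, sens.shape)
        est = op.kernel @ sens
        v_hat = int(np.argmax(np.max(np.abs(est), axis=1)))
        hits += space.roi_labels[v_hat] == space.roi_labels[v]
    return hits / n_fixtures


def _cohort_band_powers(spec: synth.CohortSpec, space: synth.SourceSpace,
                        lf: synth.LeadField, op: inv.InverseOperator,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized band powers, detected IAFs and true IAFs for one group."""
    scfg = SpectralSection()
    bps, iafs, true_iafs = [], [], []
    for i in range(spec.n_subjects):
        rec, gt = synth.simulate_subject(spec, space, lf, i)
        eset, _ = pre.preprocess_recording(rec, ica=False, seed=i)
        rts = inv.extract_roi(inv.apply_inverse(op, eset), space, fs=eset.fs)
        iaf, bp, _ = _spectral_subject(rts, scfg)
        bps.append(bp)
        iafs.append(iaf)
        true_iafs.append(gt.iaf)
    return np.asarray(bps), np.asarray(iafs), np.asarray(true_iafs)


def iaf_recovery_study(n_per_group: int = 21, duration_s: float = 62.0,
                       seed: int = 0) -> dict:
    """Recover the two groups' IAF distributions from one full cohort.

    Returns detected and ground-truth group means for the AD-like
    (8.7 +/- 0.6 Hz) and MCI-like (9.1 +/- 0.7 Hz) groups.
    """
    space = synth.make_source_space(1, seed=0)
    lf = synth.make_lead_field(space)
    op = inv.build_inverse(lf)
    out = {}
    for name, spec_fn, s in (("ad", synth.ad_like_spec, seed + 11),
                             ("mci", synth.mci_like_spec, seed + 23)):
        spec = spec_fn(n_subjects=n_per_group, duration_s=duration_s, seed=s)
        _, iafs, true_iafs = _cohort_band_powers(spec, space, lf, op)
        out[name] = {"estimated_mean": float(iafs.mean()),
                     "true_mean": float(true_iafs.mean()),
                     "abs_error": float(abs(iafs.mean() - true_iafs.mean()))}
    return out


def power_study(n_replicates: int = 100, n_per_group: int = 21,
                duration_s: float = 62.0, alpha: float = 0.05,
                seed: int = 0) -> dict:
    """Detection power for the injected AD-like posterior profile.

    For every replicate cohort the per-cell Welch t-test must reach
    p < alpha with the correct sign (alpha2 attenuated, theta enhanced in
    the AD-like group) to count as a detection.  Returns per-band minimum
    and mean power over the eight profiled posterior ROIs.
    """
    space = synth.make_source_space(1, seed=0)
    lf = synth.make_lead_field(space)
    op = inv.build_inverse(lf)
    rois = [ROI_ORDER.index(r) for r in PROFILE_ROIS]
    targets = {"alpha2": -1, "theta": +1}   # expected sign of t(AD - MCI)
    bands = {b: spe.BAND_ORDER.index(b) for b in targets}
    detect = {b: np.zeros((n_replicates, len(rois)), dtype=bool)
              for b in targets}
    for rep in range(n_replicates):
        spec_ad = synth.ad_like_spec(n_subjects=n_per_group,
                                     duration_s=duration_s,
                                     seed=seed + 1000 + rep)
        spec_mci = synth.mci_like_spec(n_subjects=n_per_group,
                                       duration_s=duration_s,
                                       seed=seed + 500_000 + rep)
        bp_ad, _, _ = _cohort_band_powers(spec_ad, space, lf, op)
        bp_mci, _, _ = _cohort_band_powers(spec_mci, space, lf, op)
        for band, sign in targets.items():
            t, p = sps.ttest_ind(bp_ad[:, rois, bands[band]],
                                 bp_mci[:, rois, bands[band]],
                                 axis=0, equal_var=False)
            detect[band][rep] = (p < alpha) & (np.sign(t) == sign)
    out = {}
    for band in targets:
        per_cell = detect[band].mean(axis=0)
        out[band] = {"min_power": float(per_cell.min()),
                     "mean_power": float(per_cell.mean())}
    return out


def connectivity_power_study(n_replicates: int = 10, n_per_group: int = 21,
                             duration_s: float = 62.0, seed: int = 0) -> float:
    """Detection probability for a single injected coupling difference.

    One group carries a strength-1 phase-lagged (pi/2) theta coupling on
    MT_L--IPC_L, the other none; a detection requires that exact
    (pair, band) cell to survive the 462-test FDR mask with the correct
    sign.  Returns the fraction of replicate cohorts detected.
    """
    from . import connectivity as con
    from . import stats as dst
    space = synth.make_source_space(1, seed=0)
    lf = synth.make_lead_field(space)
    op = inv.build_inverse(lf)
    edge = [synth.CouplingEdge("MT_L", "IPC_L", 5.5, np.pi / 2, 1.0)]

    def group_z(edges, grp_seed):
        spec = synth.mci_like_spec(n_subjects=n_per_group,
                                   duration_s=duration_s, seed=grp_seed,
                                   coupling_edges=edges)
        zs = []
        for i in range(spec.n_subjects):
            rec, _ = synth.simulate_subject(spec, space, lf, i)
            eset, _ = pre.preprocess_recording(rec, ica=False, seed=i)
            rts = inv.extract_roi(inv.apply_inverse(op, eset), space,
                                  fs=eset.fs)
            scfg = SpectralSection()
            iaf, _, _ = _spectral_subject(rts, scfg)
            _, z = con.subject_connectivity(rts, spe.BandScheme(iaf=iaf))
            zs.append(z)
        return np.asarray(zs)

    hits = 0
    for rep in range(n_replicates):
        z_a = group_z(edge, seed + 3000 + rep)
        z_b = group_z([], seed + 9000 + rep)
        table = dst.connectivity_contrasts(z_a, z_b)
        row = table[(table["pair"] == "MT_L--IPC_L")
                    & (table["band"] == "theta")].iloc[0]
        hits += bool(row["significant"] and row["direction"] == 1)
    return hits / n_replicates


def pipeline_null_fdr_study(n_replicates: int = 100, n_per_group: int = 6,
                            duration_s: float = 62.0, q: float = 0.05,
                            seed: int = 0) -> float:
    """Type-I error of the full battery on identical-generator cohorts.

    Both groups are drawn from the same MCI-like generator (different
    seeds), so every one of the 462 connectivity contrasts is null; the
    returned fraction of replicates with at least one FDR rejection
    should sit near the nominal q.
    """
    from . import connectivity as con
    from . import stats as dst
    space = synth.make_source_space(1, seed=0)
    lf = synth.make_lead_field(space)
    op = inv.build_inverse(lf)
    scfg = SpectralSection()

    def group_z(grp_seed):
        spec = synth.mci_like_spec(n_subjects=n_per_group,
                                   duration_s=duration_s, seed=grp_seed)
        zs = []
        for i in range(spec.n_subjects):
            rec, _ = synth.simulate_subject(spec, space, lf, i)
            eset, _ = pre.preprocess_recording(rec, ica=False, seed=i)
            rts = inv.extract_roi(inv.apply_inverse(op, eset), space,
                                  fs=eset.fs)
            iaf, _, _ = _spectral_subject(rts, scfg)
            _, z = con.subject_connectivity(rts, spe.BandScheme(iaf=iaf))
            zs.append(z)
        return np.asarray(zs)

    any_rejection = 0
    for rep in range(n_replicates):
        z_a = group_z(seed + 40_000 + rep)
        z_b = group_z(seed + 80_000 + rep)
        table = dst.connectivity_contrasts(z_a, z_b, q=q)
        any_rejection += bool(table["significant"].any())
    return any_rejection / n_replicates


def uniform_null_fdr_study(n_replicates: int = 1000, m: int = 462,
                           q: float = 0.05, seed: int = 0) -> float:
    """Empirical FDR of Benjamini-Hochberg under the global uniform null.

    Every replicate draws m independent uniform p-values; with all nulls
    true the false-discovery proportion is 1 whenever anything is
    rejected, so the empirical FDR estimates P(any rejection) ~ q.
    """
    rng = np.random.default_rng(seed)
    fdp = np.empty(n_replicates)
    for rep in range(n_replicates):
        _, mask = fdr_bh(rng.uniform(size=m), q=q)
        fdp[rep] = 1.0 if mask.any() else 0.0
    return float(fdp.mean())


def white_noise_ic_null(n_sims: int = 200, k_epochs: int = 30,
                        iaf: float = 9.0, seed: int = 0) -> np.ndarray:
    """97.5th percentile of |band IC| between independent white-noise
    signals, per band - the null yardstick for volume-conduction immunity."""
    from . import connectivity as con
    rng = np.random.default_rng(seed)
    scheme = spe.BandScheme(iaf=iaf)
    vals = np.empty((n_sims, len(spe.BAND_ORDER)))
    for i in range(n_sims):
        data = np.zeros((k_epochs, 12, 400))
        data[:, 0] = rng.standard_normal((k_epochs, 400))
        data[:, 1] = rng.standard_normal((k_epochs, 400))
        rts = inv.ROITimeSeries(data=data, fs=200.0)
        coef, freqs = spe.epoch_fft(rts)
        ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
        vals[i] = np.abs(con.band_ic(ic, freqs, scheme)[0])
    return np.percentile(vals, 97.5, axis=0)
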
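# Methods

`dmnrest` re-implements, as a tested library, a resting-state EEG analysis
of default-mode-network (DMN) activity contrasting a mild-AD-like with an
MCI-like group: source reconstruction of 19-channel eyes-closed EEG by
depth-weighted minimum-norm estimation, spectral power in bands anchored
to the individual alpha frequency, imaginary-coherence functional
connectivity, and the group/correlation statistics.  No patient data are
involved anywhere; a synthetic-cohort generator with full ground truth
defines the conditions under which every claim is tested.

## Forward model

The head is a three-shell concentric sphere — brain/skull/scalp radii
0.087 / 0.092 / 0.100 m, conductivities 0.33 / 0.0042 / 0.33 S/m.  The
scalp potential of a dipole is the classical Legendre series; the
per-degree shell factors are obtained by solving, for each harmonic
degree, the small radial boundary-value problem (continuity of potential
and radial current at interfaces, insulating scalp).  The series is
truncated at 200 terms (relative truncation error < 1e-12 for the
eccentricities used) and validated against the homogeneous-sphere closed
form, for which the factor is (2n+1)/n.  Because the expansion has no
monopole term the potentials are effectively referenced to the sphere
average.  Electrodes sit at classical 10-20 angular positions on the
scalp sphere; F3/F4 and P3/P4 are great-circle midpoints of Fz–F7/F8 and
Pz–T5/T6.  Mastoid positions (A1/A2, below the ear line) provide the
reference channels that synthetic recordings carry.

A note on intuition: a current dipole at the centre of a conducting
sphere produces a *nonzero* (dipolar) scalp potential — the famous
"radial sources are silent" null holds for magnetic, not electric,
recordings.  The tests assert the correct closed form.

## Source space

Twelve ROIs (medial frontal, anterior cingulate, medial temporal,
inferior parietal, posterior cingulate, precuneus; both hemispheres) are
represented by vertices scattered around fixed canonical centroids,
mirrored across the midline, with outward radial orientations
(standing in for normal constraints on a cortical surface).  Patches are
compact (3 mm scatter by default): with only 19 sensors, wider patches
blur the boundaries between neighbouring medial regions and degrade
single-dipole ROI localization; at 3 mm the depth-weighted operator
localizes ≥ 90% of random dipoles at SNR 10 into the correct ROI.

## Synthetic cohorts (the study conditions)

Each subject's per-ROI source current is a sum of

- a 1/f background (unit-RMS pink noise scaled by 4e4 pAm),
- unit-RMS AR(2) narrowband oscillators (pole radius 0.96, ≈ 2.5 Hz
  bandwidth) at delta/theta/alpha centres tied to the subject's IAF
  (IAF−7, IAF−4, IAF) and fixed beta (16.5 Hz) and gamma (35 Hz) centres,
  scaled by the group's band-amplitude profile with per-subject/ROI/band
  log-normal jitter (σ = 0.15),
- optional coupled oscillators shared between ROI pairs, the second copy
  phase-lagged via analytic-signal rotation (π/2 by default, so the
  imaginary coherence is maximal at the coupling frequency).

A pure-sinusoid mode replaces the AR(2) processes for analytic tests.
Sources project through the lead field (total ROI moment split equally
over member vertices) and i.i.d. Gaussian sensor noise (SD 2 µV) is
added.  Amplitudes (posterior alpha 1.2e5 pAm RMS, see `synth.py`) were
chosen once to give sensor signals of realistic size (channel SD ≈ 15 µV)
at a broadband SNR near 10.

Group profiles: the MCI-like group has IAF 9.1 ± 0.7 Hz and MMSE
22.7 ± 2.2; the AD-like group has IAF 8.7 ± 0.6 Hz, MMSE 14.9 ± 5.4, and
posterior (MT/IPC/PCC/PCu) multipliers delta ×1.3, theta ×1.4,
alpha ×0.7, beta ×0.8 — the alpha/beta attenuation and slow-rhythm
enhancement the analysis is meant to detect.  MMSE is an integer-clipped
Gaussian whose residual is linked to the subject's posterior-alpha
jitter (2 MMSE points per jitter SD), so correlation analyses have
signal; a zero slope decouples them by construction.  Default coupling:
PCC–PCu at 10 Hz bilaterally (strength 0.5 MCI-like vs 0.2 AD-like), and
AD-only MFC_R–MT_R (2.5 Hz) and MT_R–PCC_R (5.5 Hz) edges, echoing the
enhanced slow-band medial-temporal connectivity expected in AD.

What the generator does *not* emulate: real cortical geometry and BEM
volume conduction, non-stationarity and drowsiness, heartbeat artifacts,
eye movements other than blink-like transients, line noise, and
electrode impedance drift.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the stated
statistical structure, not clinical performance on real EEG.

## Preprocessing

Fixed order: mastoid re-reference → zero-phase 4th-order Butterworth
band-pass 1–40 Hz (applied forward-backward; measured stop-band
attenuation ≥ 40 dB at 0.5, 60 and 70 Hz) → consecutive 2-s epochs →
seeded FastICA (tolerance 1e-6, ≤ 500 iterations; the algorithm is a
contract — any decomposition reproducing the input to 1e-6 and passing
the known-mixing recovery test would do) → two-criteria component
rejection → uniform random selection of 30 epochs.

Rejection criteria replace visual inspection with quantified features:

1. *ocular*: frontal-gradient score > 0.85 (power-weighted mean of the
   normalized anterior coordinate of the topography) **and** fitted
   log-power slope < −0.40 dB/Hz over 1–40 Hz;
2. *myogenic*: topography kurtosis > 6 **and** 20–40 Hz power fraction
   > 0.60.

Thresholds were calibrated on artifact-free synthetic cohorts (0 false
rejections across calibration subjects, injected components always
flagged; frontal ocular components score ≈ 0.93 vs ≤ 0.78 for clean
components, muscle bursts reach kurtosis ≈ 14 and power fraction ≈ 0.9).
They are configuration values, not constants.

## Inverse operator

K = R Lᵀ (L R Lᵀ + λ²C)⁻¹ with fixed (normal) orientations, depth
weights w_v = (‖l_v‖²)^(−γ) (γ = 0.5, capped at 100× the smallest
weight), λ² = 0.33, and identity noise covariance by default.  R is
rescaled so trace(L R Lᵀ) = trace(C), making λ² independent of gain
units; the identity-matrix limit cases (K = I/(1+λ²)) are unaffected.
ROI courses are plain signed means over member vertices — no sign
flipping, since radial orientations give coherent signs within a patch;
a cancellation test documents why the convention matters.  Reported
activation is the mean rectified current (signed means of oscillatory
sources vanish).

## Spectral analysis

Per-epoch periodograms with a 512-point FFT of the 400-sample epochs
(bin spacing exactly 200/512 = 0.390625 Hz), Hann window by default
(rectangular mode for Parseval-exact checks), averaged over the 30
selected epochs.  IAF = highest local maximum of the mean posterior
(IPC/PCC/PCu) spectrum in 7–13 Hz, ties toward the lower frequency;
without a local maximum the power-weighted mean frequency is used with a
warning.  Bands: delta [IAF−8, IAF−6), theta [IAF−6, IAF−2),
alpha1 [IAF−2, IAF), alpha2 [IAF, IAF+2), beta1 [13, 20), beta2
[20, 30), gamma [30, 40].  Edges below 1 Hz are clipped; for IAF > 11 the
IAF-anchored bands take precedence over beta1.  Bins in the unassigned
(IAF+2, 13) Hz gap are excluded from every band and, by default, from
the normalizing total, so normalized band vectors sum to exactly 1;
including the gap in the denominator is a configuration switch.
A structural consequence worth knowing: because every ROI's bands sum to
one, the Region main effect of a Band×Region ANOVA on normalized powers
is identically zero — region differences live in the interactions.

## Connectivity

With per-epoch ROI spectra X_k(f) (same FFT path as the power spectra),
S_xy = Σ_k X_k Y_k*, and IC(f) = Im[S_xy/√(S_xx S_yy)] — the standard
cross-/auto-spectral-sum estimator, bounded by [−1, 1]
and exactly zero for any zero-lag mixture.  Band values are signed means
of per-bin IC (an absolute-value mode exists; the signed mean preserves
the direction of group differences but lets opposite-signed bins cancel
— documented and tested).  Fisher z = atanh(IC) (inputs clipped at
1−1e-12) stabilizes variance before subject averaging and testing.
Zero-power bins are masked to 0 so band averages stay defined.

## Statistics

- Activation: two-way mixed ANOVA (Group between, Region within), via
  pingouin, Greenhouse–Geisser correction on by default.
- Normalized power: three-way balanced split-plot (Group × Band ×
  Region, Band and Region repeated), implemented in-package because no
  installed library covers one-between/two-within designs; every within
  effect is tested against its own Subject-interaction stratum with a GG
  epsilon from the pooled within-group covariance of the appropriate
  contrasts.  The implementation is cross-checked against pingouin on
  collapsed two-way designs (exact F agreement) and requires a complete,
  balanced layout.
- Post-hoc: paired t contrasts with Bonferroni adjustment.
- Connectivity: two-sample t on Fisher-z per (pair, band) — z is the
  variance-stabilized scale, which is why it, not raw IC, feeds the
  tests — with Benjamini–Hochberg correction over all 66 × 7 = 462
  tests (statsmodels implementation; a brute-force step-up oracle backs
  it in the tests) and the sign of each difference retained.
- Correlations: Pearson r between MMSE and normalized powers / Fisher-z
  values, pooled over both groups (the interesting range of the
  covariate spans the groups).

## Problem sizes and numerical choices

Replicated studies (100-replicate detection power at n = 21/group,
1000-replicate uniform-null FDR calibration, a 100-replicate
identical-generator null battery through the full pipeline at n = 6/group,
100-fixture localization) run on reduced
per-subject problem sizes — 62-s recordings, one vertex per ROI, ICA
skipped when no artifacts are injected — which leaves the statistical
conditions (group sizes, profiles, epoch budget of 30) untouched.
Determinism is end-to-end: all randomness flows from explicit seeds
(per-subject generators are seeded by (cohort seed, subject index)), and
a pipeline re-run from the same configuration reproduces bit-identical
artifacts (HDF5 written without timestamps, EDF with a fixed start
date).  Degenerate inputs are handled explicitly: zero-power spectra
fall back to weighted-mean IAF, zero auto-spectra mask IC bins,
rank-deficient data reduce the ICA component count, all-flagged
component sets raise instead of returning empty data, and non-PD noise
covariances are rejected.

## Known limitations

Spherical geometry and radial orientations only; a single (identity by
default) noise covariance rather than a measured one; no eyes-open
condition; no sLORETA-style variant (the signed no-flip ROI mean is the
single extraction convention, with the leading-eigenvector alternative
left as future work); the three-way ANOVA requires balanced groups;
detection-power results quantify sensitivity to the generator's effect
sizes, not to any particular clinical effect.
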
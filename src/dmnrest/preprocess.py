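"""Sensor-space preprocessing: referencing, filtering, epoching, ICA denoising.

The stage order is fixed: re-reference -> band-pass filter -> segment into
2-s epochs -> ICA decomposition -> component rejection -> random epoch
selection.  Component rejection replaces visual inspection with two
quantified criteria:

1. ocular: far-frontal topography (frontal-gradient score above threshold)
   together with a smoothly decreasing power spectrum (fitted log-power
   slope below threshold);
2. myogenic: spatially focal topography (high spatial kurtosis) together
   with a high 20-40 Hz / 1-40 Hz power ratio.

Default thresholds were calibrated on artifact-free synthetic cohorts so
that the false-rejection rate stays below 5% while injected ocular and
muscle components are reliably flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from . import io as _io
from .montage import CHANNELS_1020, electrode_positions

logger = logging.getLogger(__name__)


class MissingChannelError(ValueError):
    """A required 10-20 channel is absent from the input file."""


@dataclass
class EEGRecording:
    """A 19-channel scalp EEG recording in microvolts.

    ``mastoid`` optionally carries the two mastoid (A1/A2) reference
    signals produced by the synthetic forward model; ``artifacts`` records
    injected artifact events (kind, onset time, duration, channel) so that
    rejection efficacy can be asserted against ground truth.
    """

    data: np.ndarray                      # (19, n_samples), microvolts
    fs: float                             # Hz
    channel_labels: tuple[str, ...] = CHANNELS_1020
    reference: str = "common"
    mastoid: np.ndarray | None = None     # (2, n_samples) or None
    artifacts: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if set(self.channel_labels) != set(CHANNELS_1020):
            missing = sorted(set(CHANNELS_1020) - set(self.channel_labels))
            raise MissingChannelError(f"missing 10-20 channels: {missing}")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def in_canonical_order(self) -> "EEGRecording":
        if self.channel_labels == CHANNELS_1020:
            return self
        order = [self.channel_labels.index(ch) for ch in CHANNELS_1020]
        return replace(self, data=self.data[order], channel_labels=CHANNELS_1020)


@dataclass
class EpochSet:
    """Non-overlapping 2-s segments of a recording, (K, channels, samples)."""

    epochs: np.ndarray
    fs: float
    epoch_length_s: float = 2.0
    channel_labels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        n = int(round(self.fs * self.epoch_length_s))
        if self.epochs.ndim != 3 or self.epochs.shape[2] != n:
            raise ValueError(
                f"epochs must be (K, channels, {n}) for {self.epoch_length_s} s "
                f"at {self.fs} Hz; got {self.epochs.shape}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class ComponentDecomposition:
    """ICA decomposition of an epoch set with per-component features."""

    mixing: np.ndarray          # (channels, components) topographies
    activations: np.ndarray     # (components, total samples)
    mean: np.ndarray            # (channels,) removed channel means
    fs: float
    epoch_shape: tuple[int, int, int]
    channel_labels: tuple[str, ...]
    method: str = "fastica"
    frontal_gradient: np.ndarray | None = None
    spectral_slope: np.ndarray | None = None
    spatial_kurtosis: np.ndarray | None = None
    hf_power_ratio: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Back-project, optionally keeping only the given components."""
        if keep is None:
            x = self.mixing @ self.activations
        else:
            x = self.mixing[:, keep] @ self.activations[keep]
        return x + self.mean[:, None]


@dataclass(frozen=True)
class RejectionThresholds:
    """Calibrated defaults for the two component-rejection criteria."""

    frontal_gradient_min: float = 0.85   # criterion 1: far-frontal topography
    spectral_slope_max: float = -0.40    # criterion 1: dB per Hz, 1-40 Hz fit
    spatial_kurtosis_min: float = 6.0    # criterion 2: focal topography
    hf_power_ratio_min: float = 0.60     # criterion 2: 20-40 Hz / 1-40 Hz


def read_recording(path: str | Path, fmt: str | None = None,
                   units: str | None = None) -> EEGRecording:
    """Load a recording from EDF or CSV and canonicalize channel order.

    CSV carries no unit metadata, so ``units`` must be declared ("uV");
    EDF stores physical dimensions and needs no declaration.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "edf":
        data, labels, fs = _io.read_edf(path)
    elif fmt == "csv":
        if units is None:
            raise ValueError(
                "CSV input has no unit metadata: declare units explicitly "
                "(units='uV')")
        if units not in ("uV", "µV"):
            raise ValueError(f"unsupported units {units!r}; expected microvolts")
        data, labels, fs = _io.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")

    core = [lab for lab in labels if lab in CHANNELS_1020]
    missing = sorted(set(CHANNELS_1020) - set(core))
    if missing:
        raise MissingChannelError(f"missing 10-20 channels: {missing}")
    mastoid_rows = [i for i, lab in enumerate(labels) if lab in ("A1", "A2")]
    mastoid = data[mastoid_rows] if len(mastoid_rows) == 2 else None
    rows = [labels.index(ch) for ch in CHANNELS_1020]
    return EEGRecording(data=data[rows], fs=fs, channel_labels=CHANNELS_1020,
                        mastoid=mastoid)


def rereference(rec: EEGRecording) -> EEGRecording:
    """Reference every channel to the average of the two linked mastoids.

    Idempotent: the re-referenced mastoid average is identically zero, so a
    second pass subtracts nothing.  Without mastoid signals the operation
    is a logged no-op.
    """
    if rec.mastoid is None:
        logger.warning("no mastoid signals available; re-referencing skipped")
        return rec
    ref = rec.mastoid.mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref, mastoid=rec.mastoid - ref,
                   reference="linked_mastoid_average")


def bandpass(rec: EEGRecording, lo: float = 1.0, hi: float = 40.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter (forward-backward).

    The default 4th-order design applied forward and backward yields an
    effective 8th-order magnitude response with > 40 dB attenuation at
    lo/2 and at (hi + fs/2)/2 for the 1-40 Hz band at 200 Hz.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    mastoid = (signal.sosfiltfilt(sos, rec.mastoid, axis=1)
               if rec.mastoid is not None else None)
    return replace(rec, data=data, mastoid=mastoid)


def segment(rec: EEGRecording, length_s: float = 2.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; the remainder is dropped."""
    n = int(round(rec.fs * length_s))
    if rec.n_samples < n:
        raise ValueError("recording shorter than one epoch")
    k = rec.n_samples // n
    epochs = rec.data[:, :k * n].reshape(rec.data.shape[0], k, n).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), fs=rec.fs, epoch_length_s=length_s,
                    channel_labels=rec.channel_labels)


def _component_features(mixing: np.ndarray, activations: np.ndarray, fs: float,
                        channel_labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    pos = electrode_positions(labels=tuple(channel_labels))
    y = pos[:, 1]
    y01 = (y - y.min()) / (y.max() - y.min())
    n_comp = mixing.shape[1]
    frontal = np.empty(n_comp)
    slope = np.empty(n_comp)
    kurt = np.empty(n_comp)
    hf = np.empty(n_comp)
    for c in range(n_comp):
        topo = mixing[:, c]
        w = topo ** 2
        frontal[c] = float(w @ y01 / w.sum())
        kurt[c] = float(stats.kurtosis(topo / np.linalg.norm(topo)))
        f, p = signal.welch(activations[c], fs=fs, nperseg=min(512, activations.shape[1]))
        band = (f >= 1.0) & (f <= 40.0)
        logp = 10 * np.log10(np.maximum(p[band], 1e-30))
        slope[c] = float(np.polyfit(f[band], logp, 1)[0])
        total = p[(f >= 1.0) & (f <= 40.0)].sum()
        high = p[(f >= 20.0) & (f <= 40.0)].sum()
        hf[c] = float(high / total) if total > 0 else 0.0
    return {"frontal_gradient": frontal, "spectral_slope": slope,
            "spatial_kurtosis": kurt, "hf_power_ratio": hf}


def decompose(eset: EpochSet, n_components: int | None = None,
              seed: int = 0) -> ComponentDecomposition:
    """Seeded FastICA of the concatenated epochs.

    The decomposition contract is reconstruction: mixing x activations
    (plus channel means) reproduces the input to ~1e-6 relative error when
    the component count equals the data rank.  Rank-deficient input
    reduces the component count with a warning.
    """
    n_ch = eset.epochs.shape[1]
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("cannot extract more components than channels")
    x = eset.epochs.transpose(1, 0, 2).reshape(n_ch, -1)
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    rank = int(np.linalg.matrix_rank(xc, tol=1e-8 * np.abs(xc).max()))
    if rank < n_components:
        logger.warning("rank-deficient input (rank %d); reducing components "
                       "from %d", rank, n_components)
        n_components = rank
    ica = FastICA(n_components=n_components, random_state=seed, tol=1e-6,
                  max_iter=500, whiten="unit-variance")
    sources = ica.fit_transform(xc.T).T          # (components, samples)
    mixing = ica.mixing_                         # (channels, components)
    try:
        feats = _component_features(mixing, sources, eset.fs,
                                    eset.channel_labels)
    except KeyError:
        # non-10-20 labels (e.g. algorithmic test data): no topography scores
        feats = {}
    return ComponentDecomposition(
        mixing=mixing, activations=sources, mean=mean, fs=eset.fs,
        epoch_shape=eset.epochs.shape, channel_labels=eset.channel_labels,
        **feats)


def score_and_reject(dec: ComponentDecomposition,
                     thresholds: RejectionThresholds = RejectionThresholds(),
                     ) -> tuple[EpochSet, list[int]]:
    """Flag artifact components by the two criteria and back-project the rest."""
    t = thresholds
    ocular = ((dec.frontal_gradient > t.frontal_gradient_min)
              & (dec.spectral_slope < t.spectral_slope_max))
    myogenic = ((dec.spatial_kurtosis > t.spatial_kurtosis_min)
                & (dec.hf_power_ratio > t.hf_power_ratio_min))
    rejected = np.flatnonzero(ocular | myogenic)
    if rejected.size == dec.n_components:
        raise ValueError("all components flagged as artifacts; refusing to "
                         "return empty data")
    keep = np.setdiff1d(np.arange(dec.n_components), rejected)
    x = dec.reconstruct(keep=keep)
    k, n_ch, n = dec.epoch_shape
    epochs = x.reshape(n_ch, k, n).transpose(1, 0, 2)
    eset = EpochSet(epochs=epochs, fs=dec.fs, epoch_length_s=n / dec.fs,
                    channel_labels=dec.channel_labels)
    return eset, [int(i) for i in rejected]


def select_epochs(eset: EpochSet, n: int = 30, seed: int = 0) -> EpochSet:
    """Uniform random subset of n epochs, chronological order preserved."""
    if eset.n_epochs < n:
        raise ValueError(
            f"only {eset.n_epochs} epochs available, {n} requested "
            f"(shortfall {n - eset.n_epochs})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(eset.n_epochs, size=n, replace=False))
    return replace(eset, epochs=eset.epochs[idx])


def preprocess_recording(rec: EEGRecording, *, lo: float = 1.0, hi: float = 40.0,
                         filter_order: int = 4, epoch_length_s: float = 2.0,
                         n_select: int = 30, ica: bool = True,
                         n_components: int | None = None, seed: int = 0,
                         thresholds: RejectionThresholds = RejectionThresholds(),
                         ) -> tuple[EpochSet, list[int]]:
    """Run the fixed preprocessing chain on one recording.

    Returns the selected artifact-free epochs and the indices of rejected
    ICA components (empty when ``ica`` is disabled).
    """
    rec = rereference(rec)
    rec = bandpass(rec, lo=lo, hi=hi, order=filter_order)
    eset = segment(rec, length_s=epoch_length_s)
    rejected: list[int] = []
    if ica:
        dec = decompose(eset, n_components=n_components, seed=seed)
        eset, rejected = score_and_reject(dec, thresholds=thresholds)
    eset = select_epochs(eset, n=n_select, seed=seed)
    return eset, rejected
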
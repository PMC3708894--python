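"""Imaginary-coherence functional connectivity between ROI pairs.

For ROI source spectra X_k(f), Y_k(f) over the K selected 2-s epochs, the
cross- and auto-spectral sums S_xy = sum_k X_k Y_k*, S_xx = sum_k |X_k|^2
give the imaginary coherence

    I_xy(f) = Im[ S_xy(f) / sqrt(S_xx(f) S_yy(f)) ]

which vanishes for any zero-lag (volume-conduction-like, instantaneous)
mixture of common sources and is bounded by [-1, 1] (Cauchy-Schwarz).
Band values are signed arithmetic means of the per-bin I_xy over the
band's bins; Fisher's z = atanh(I) variance-stabilizes the values before
averaging over the N subjects of a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inverse import ROITimeSeries
from .montage import ROI_ORDER, pair_label, roi_pairs
from .spectral import BAND_ORDER, BandScheme, bin_band_indices, epoch_fft

logger = logging.getLogger(__name__)

PAIRS: list[tuple[str, str]] = roi_pairs()
PAIR_LABELS: tuple[str, ...] = tuple(pair_label(a, b) for a, b in PAIRS)
_PAIR_IDX = [(ROI_ORDER.index(a), ROI_ORDER.index(b)) for a, b in PAIRS]


@dataclass
class CrossSpectra:
    """Epoch-summed cross- and auto-spectra for the 66 canonical pairs."""

    sxy: np.ndarray             # (66, n_bins) complex, sum_k X_k Y_k*
    sxx: np.ndarray             # (12, n_bins) real >= 0, sum_k |X_k|^2
    freqs: np.ndarray
    n_epochs: int
    pairs: tuple[str, ...] = PAIR_LABELS

    def __post_init__(self) -> None:
        if self.n_epochs < 2:
            raise ValueError("coherence needs at least 2 epochs")
        if np.any(self.sxx < -1e-12):
            raise ValueError("auto-spectra must be non-negative")


def cross_spectra(coef: np.ndarray, freqs: np.ndarray) -> CrossSpectra:
    """Build cross-spectra from per-epoch complex ROI spectra (K, 12, bins)."""
    if coef.shape[0] < 2:
        raise ValueError("coherence needs at least 2 epochs")
    sxx = np.sum(np.abs(coef) ** 2, axis=0)
    i_idx = np.array([i for i, _ in _PAIR_IDX])
    j_idx = np.array([j for _, j in _PAIR_IDX])
    sxy = np.sum(coef[:, i_idx, :] * np.conj(coef[:, j_idx, :]), axis=0)
    return CrossSpectra(sxy=sxy, sxx=np.real(sxx), freqs=freqs,
                        n_epochs=coef.shape[0])


def imaginary_coherence(cs: CrossSpectra) -> np.ndarray:
    """Per-pair, per-bin imaginary coherence (66, n_bins).

    Bins where either auto-spectrum vanishes are set to 0 (masked), so
    that band averages remain defined.
    """
    i_idx = np.array([i for i, _ in _PAIR_IDX])
    j_idx = np.array([j for _, j in _PAIR_IDX])
    denom2 = cs.sxx[i_idx, :] * cs.sxx[j_idx, :]
    ic = np.zeros(cs.sxy.shape)
    ok = denom2 > 0
    if not ok.all():
        logger.warning("%d zero-power bins masked in imaginary coherence",
                       int((~ok).sum()))
    ic[ok] = np.imag(cs.sxy[ok]) / np.sqrt(denom2[ok])
    return ic


def band_ic(ic: np.ndarray, freqs: np.ndarray, scheme: BandScheme) -> np.ndarray:
    """Signed arithmetic mean of per-bin IC over each band's bins, (66, 7).

    Sign is retained so that the direction of group differences survives
    averaging; pass ``np.abs(ic)`` for the magnitude-aggregation variant.
    """
    idx = bin_band_indices(freqs, scheme)
    out = np.zeros((ic.shape[0], len(BAND_ORDER)))
    for k in range(len(BAND_ORDER)):
        m = idx == k
        if m.any():
            out[:, k] = ic[:, m].mean(axis=1)
    return out


def fisher_z(ic: np.ndarray) -> np.ndarray:
    """Fisher's variance-stabilizing transform z = atanh(IC).

    Values at or beyond |IC| = 1 are clipped to 1 - 1e-12 with a warning
    so z stays finite.
    """
    ic = np.asarray(ic, dtype=float)
    lim = 1.0 - 1e-12
    if np.any(np.abs(ic) >= 1.0):
        logger.warning("IC magnitude >= 1 clipped before Fisher z")
    return np.arctanh(np.clip(ic, -lim, lim))


@dataclass
class GroupConnectivity:
    """Grand-averaged Fisher-z connectivity over the N subjects of a group."""

    mean_z: np.ndarray          # (66, 7)
    n_subjects: int
    pairs: tuple[str, ...] = PAIR_LABELS
    bands: tuple[str, ...] = BAND_ORDER

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("group average needs N >= 2 subjects")


def group_average(z: np.ndarray) -> GroupConnectivity:
    """Grand average of per-subject z values, (N, 66, 7) -> (66, 7)."""
    z = np.asarray(z, dtype=float)
    return GroupConnectivity(mean_z=z.mean(axis=0), n_subjects=z.shape[0])


def subject_connectivity(rts: ROITimeSeries, scheme: BandScheme,
                         window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """Band imaginary coherence and Fisher z for one subject, (66, 7) each."""
    coef, freqs = epoch_fft(rts, window=window)
    cs = cross_spectra(coef, freqs)
    ic = imaginary_coherence(cs)
    bic = band_ic(ic, freqs, scheme)
    return bic, fisher_z(bic)


@dataclass
class ConnectivityTensor:
    """Cohort connectivity, subject x 66 pairs x 7 bands (IC and Fisher z)."""

    ic: np.ndarray
    z: np.ndarray
    subjects: list[str]
    groups: list[str]
    pairs: tuple[str, ...] = PAIR_LABELS
    bands: tuple[str, ...] = BAND_ORDER

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for s, (sub, grp) in enumerate(zip(self.subjects, self.groups)):
            for p, pair in enumerate(self.pairs):
                for b, band in enumerate(self.bands):
                    rows.append({"subject": sub, "group": grp, "pair": pair,
                                 "band": band, "ic": self.ic[s, p, b],
                                 "z": self.z[s, p, b]})
        return pd.DataFrame(rows)
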
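"""Spectral analysis of ROI currents: FFT power, IAF, anchored band powers.

Per-epoch periodograms use a 512-point FFT of the 400-sample (2 s, 200 Hz)
epochs — the unique power-of-two length whose bin spacing, 200/512 =
0.390625 Hz, rounds to the 0.39 Hz working resolution — averaged across
the K selected epochs.  A Hann window is the default (leakage control); a
rectangular window is available for exact Parseval/analytic checks.

Band edges are anchored to the individual alpha frequency (IAF):
delta [IAF-8, IAF-6), theta [IAF-6, IAF-2), alpha1 [IAF-2, IAF),
alpha2 [IAF, IAF+2), plus fixed beta1 [13, 20), beta2 [20, 30) and
gamma [30, 40].  Edges below 1 Hz are clipped (with a warning); if
IAF+2 exceeds 13 Hz the IAF-anchored bands take precedence over beta1.
Bins in the unassigned gap (IAF+2, 13) Hz are excluded from every band
and, by default, from the normalizing total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inverse import ROITimeSeries
from .montage import POSTERIOR_ROIS, ROI_ORDER

logger = logging.getLogger(__name__)

NFFT = 512
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha1", "alpha2",
                               "beta1", "beta2", "gamma")


@dataclass
class Spectrum:
    """Epoch-averaged one-sided power spectra, ROI x bin (pAm^2/Hz)."""

    freqs: np.ndarray           # bin centres, Hz, spacing fs/NFFT exactly
    power: np.ndarray           # (n_rois, n_bins), >= 0
    n_epochs: int
    roi_labels: tuple[str, ...] = ROI_ORDER

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def roi(self, roi: str) -> np.ndarray:
        return self.power[self.roi_labels.index(roi)]


@dataclass(frozen=True)
class BandScheme:
    """IAF-anchored seven-band scheme."""

    iaf: float

    def edges(self) -> dict[str, tuple[float, float]]:
        """Band -> [lo, hi) edges in Hz (gamma's upper edge inclusive)."""
        a = self.iaf
        lo_d = a - 8.0
        if lo_d < 1.0:
            logger.warning("IAF %.2f Hz puts the delta edge below 1 Hz; "
                           "clipping at 1 Hz", a)
        return {
            "delta": (max(1.0, lo_d), a - 6.0),
            "theta": (max(1.0, a - 6.0), a - 2.0),
            "alpha1": (a - 2.0, a),
            "alpha2": (a, a + 2.0),
            "beta1": (max(13.0, a + 2.0), 20.0),
            "beta2": (20.0, 30.0),
            "gamma": (30.0, 40.0),
        }

    def gap(self) -> tuple[float, float]:
        """The unassigned interval (IAF+2, 13) Hz; empty when IAF >= 11."""
        return (self.iaf + 2.0, 13.0)


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(n)
    if kind in ("rect", "rectangular", "boxcar"):
        return np.ones(n)
    raise ValueError(f"unknown window {kind!r}")


def epoch_fft(rts: ROITimeSeries, window: str = "hann",
              nfft: int = NFFT) -> tuple[np.ndarray, np.ndarray]:
    """Windowed, zero-padded rFFT of every epoch and ROI.

    Returns (coefficients of shape (K, n_rois, nfft//2+1), bin centres).
    Shared by the power-spectral and cross-spectral (coherence) paths so
    both use the same FFT convention.
    """
    n = rts.data.shape[2]
    if nfft < n:
        raise ValueError("nfft must be >= epoch length")
    w = _window(n, window)
    coef = np.fft.rfft(rts.data * w[None, None, :], n=nfft, axis=2)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rts.fs)
    return coef, freqs


def epoch_spectrum(rts: ROITimeSeries, window: str = "hann",
                   nfft: int = NFFT) -> Spectrum:
    """Per-epoch periodograms averaged over the K epochs.

    One-sided density scaling: with a rectangular window the integral of
    the spectrum over frequency equals the epoch mean-square amplitude
    (Parseval).
    """
    n = rts.data.shape[2]
    w = _window(n, window)
    coef, freqs = epoch_fft(rts, window=window, nfft=nfft)
    p = np.abs(coef) ** 2
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    p = p * scale[None, None, :] / (rts.fs * np.sum(w ** 2))
    return Spectrum(freqs=freqs, power=p.mean(axis=0), n_epochs=rts.n_epochs)


def detect_iaf(spec: Spectrum, search_lo: float = 7.0, search_hi: float = 13.0,
               rois: tuple[str, ...] = POSTERIOR_ROIS) -> float:
    """Individual alpha frequency: peak of the mean posterior spectrum.

    The highest local maximum within the search window wins, ties broken
    toward the lower frequency; with no local maximum (flat or monotone
    spectrum) the power-weighted mean frequency of the window is returned
    with a warning.
    """
    if search_lo < spec.freqs[0] or search_hi > spec.freqs[-1]:
        raise ValueError("search window outside the spectrum range")
    rows = [spec.roi_labels.index(r) for r in rois]
    mean_p = spec.power[rows].mean(axis=0)
    win = np.flatnonzero((spec.freqs >= search_lo) & (spec.freqs <= search_hi))
    cand = [i for i in win
            if 0 < i < len(mean_p) - 1
            and mean_p[i] > mean_p[i - 1] and mean_p[i] >= mean_p[i + 1]]
    if not cand:
        logger.warning("no spectral peak in [%g, %g] Hz; falling back to the "
                       "power-weighted mean frequency", search_lo, search_hi)
        tot = mean_p[win].sum()
        if tot <= 0:
            return float(0.5 * (search_lo + search_hi))
        return float(np.sum(spec.freqs[win] * mean_p[win]) / tot)
    best = cand[int(np.argmax(mean_p[cand]))]
    return float(spec.freqs[best])


def bin_band_indices(freqs: np.ndarray, scheme: BandScheme) -> np.ndarray:
    """Band index per frequency bin (-1 for unassigned bins).

    Half-open [lo, hi) assignment in band order, so the IAF-anchored bands
    take precedence when alpha2 reaches past 13 Hz; the gamma band
    includes its 40 Hz upper edge.
    """
    edges = scheme.edges()
    out = np.full(freqs.shape, -1, dtype=int)
    for k, band in enumerate(BAND_ORDER):
        lo, hi = edges[band]
        if band == "gamma":
            m = (freqs >= lo) & (freqs <= hi)
        else:
            m = (freqs >= lo) & (freqs < hi)
        out[m & (out == -1)] = k
    return out


def band_power(spec: Spectrum, scheme: BandScheme,
               return_gap: bool = False):
    """Integrated power per ROI and band, (n_rois, 7), pAm^2.

    ``return_gap`` additionally returns the power in the unassigned
    (IAF+2, 13) Hz interval (needed when the normalizing total is
    configured to include it).
    """
    idx = bin_band_indices(spec.freqs, scheme)
    bp = np.empty((spec.power.shape[0], len(BAND_ORDER)))
    for k in range(len(BAND_ORDER)):
        m = idx == k
        bp[:, k] = spec.power[:, m].sum(axis=1) * spec.df
    if not return_gap:
        return bp
    g_lo, g_hi = scheme.gap()
    gm = (spec.freqs >= g_lo) & (spec.freqs < g_hi) & (idx == -1)
    gap = spec.power[:, gm].sum(axis=1) * spec.df
    return bp, gap


def normalize(bp: np.ndarray, gap: np.ndarray | None = None) -> np.ndarray:
    """Normalize band powers by the total power from delta to gamma.

    By default the total is the sum of the seven bands (rows then sum to
    one exactly); passing the gap power includes the unassigned interval
    in the denominator.
    """
    bp = np.asarray(bp, dtype=float)
    total = bp.sum(axis=-1)
    if gap is not None:
        total = total + gap
    if np.any(total <= 0):
        raise ValueError("total power must be positive")
    return bp / total[..., None]


def peak_frequency(spec: Spectrum, roi: str, lo: float = 1.0,
                   hi: float = 40.0) -> float:
    """Argmax frequency of one ROI's spectrum in [lo, hi]; ties -> lower."""
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    p = spec.roi(roi)[m]
    return float(spec.freqs[m][int(np.argmax(p))])


@dataclass
class BandPowerTable:
    """Normalized band powers for a cohort, subject x ROI x band."""

    values: np.ndarray              # (n_subjects, 12, 7)
    subjects: list[str]
    groups: list[str]
    roi_labels: tuple[str, ...] = ROI_ORDER
    bands: tuple[str, ...] = BAND_ORDER
    iaf: np.ndarray | None = None   # per-subject detected IAF

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for s, (sub, grp) in enumerate(zip(self.subjects, self.groups)):
            for r, roi in enumerate(self.roi_labels):
                for b, band in enumerate(self.bands):
                    rows.append({"subject": sub, "group": grp, "roi": roi,
                                 "band": band, "value": self.values[s, r, b]})
        return pd.DataFrame(rows)
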
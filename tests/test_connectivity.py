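import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmnrest import connectivity as con
from dmnrest import spectral as spe
from dmnrest.inverse import ROITimeSeries


def rts_pair(x, y, fs=200.0, n=400):
    """Put signal x in ROI 0 and y in ROI 1 (epochs cut from long signals)."""
    k = len(x) // n
    data = np.zeros((k, 12, n))
    data[:, 0, :] = x[:k * n].reshape(k, n)
    data[:, 1, :] = y[:k * n].reshape(k, n)
    return ROITimeSeries(data=data, fs=fs)


def pair_index(a, b):
    return con.PAIR_LABELS.index(f"{a}--{b}")


P01 = 0  # canonical index of the ROI0--ROI1 pair (MFC_L--MFC_R)


def quarter_lag_pair(f0=12.5, k=8, fs=200.0, n=400):
    """f0 = 12.5 Hz is an exact bin of both the 400-sample epoch and the
    512-point transform, so rectangular-window spectra are leakage-free."""
    t = np.arange(k * n) / fs
    x = np.cos(2 * np.pi * f0 * t)
    y = np.cos(2 * np.pi * f0 * t - np.pi / 2)
    return rts_pair(x, y), f0


class TestCrossSpectra:
    def test_self_pair_real_and_equal_to_autospectrum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8 * 400)
        rts = rts_pair(x, x.copy())
        coef, freqs = spe.epoch_fft(rts)
        cs = con.cross_spectra(coef, freqs)
        assert np.allclose(cs.sxy[P01].imag, 0.0, atol=1e-9)
        assert np.allclose(cs.sxy[P01].real, cs.sxx[0], rtol=1e-12)

    def test_pure_delay_phase(self):
        """Delaying by tau samples rotates the cross-spectrum phase by
        2 pi f tau at the signal's bin."""
        f0, tau = 12.5, 3
        t = np.arange(8 * 400 + tau) / 200.0
        s = np.cos(2 * np.pi * f0 * t)
        rts = rts_pair(s[tau:], s[:-tau])
        coef, freqs = spe.epoch_fft(rts, window="rect")
        cs = con.cross_spectra(coef, freqs)
        k = int(round(f0 / (freqs[1] - freqs[0])))
        expected = 2 * np.pi * f0 * tau / 200.0
        assert np.angle(cs.sxy[P01, k]) == pytest.approx(expected, abs=1e-9)

    def test_single_epoch_rejected(self):
        rng = np.random.default_rng(1)
        rts = rts_pair(rng.standard_normal(400), rng.standard_normal(400))
        coef, freqs = spe.epoch_fft(rts)
        with pytest.raises(ValueError, match="2 epochs"):
            con.cross_spectra(coef, freqs)

    def test_white_noise_coherency_shrinks_with_epochs(self):
        """Independent white noise over K=30 epochs: coherency magnitude is
        O(1/sqrt(K)) and imaginary coherence near zero."""
        rng = np.random.default_rng(2)
        rts = rts_pair(rng.standard_normal(30 * 400),
                       rng.standard_normal(30 * 400))
        coef, freqs = spe.epoch_fft(rts)
        cs = con.cross_spectra(coef, freqs)
        coh = np.abs(cs.sxy[P01]) / np.sqrt(cs.sxx[0] * cs.sxx[1])
        assert np.mean(coh) < 3.0 / np.sqrt(30)
        ic = con.imaginary_coherence(cs)
        assert np.abs(np.mean(ic[P01])) < 0.05


class TestImaginaryCoherence:
    def test_identical_signals_give_zero_everywhere(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10 * 400)
        coef, freqs = spe.epoch_fft(rts_pair(x, x.copy()))
        ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
        assert np.allclose(ic[P01], 0.0, atol=1e-9)

    def test_instantaneous_mixture_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30 * 400)
        z = rng.standard_normal(30 * 400)
        coef, freqs = spe.epoch_fft(rts_pair(x, 0.7 * x + 0.5 * z))
        ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
        assert np.abs(ic[P01]).mean() < 0.12

    def test_quarter_cycle_lag_gives_unit_ic(self):
        rts, f0 = quarter_lag_pair()
        coef, freqs = spe.epoch_fft(rts, window="rect")
        ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
        k = int(round(f0 / (freqs[1] - freqs[0])))
        assert ic[P01, k] == pytest.approx(1.0, abs=1e-9)

    def test_lag_sign_flips_ic_sign(self):
        t = np.arange(8 * 400) / 200.0
        x = np.cos(2 * np.pi * 12.5 * t)
        y = np.cos(2 * np.pi * 12.5 * t + np.pi / 2)   # y leads x
        coef, freqs = spe.epoch_fft(rts_pair(x, y), window="rect")
        ic = con.imaginary_coherence(con.cross_spectra(coef, freqs))
        k = int(round(12.5 / (freqs[1] - freqs[0])))
        assert ic[P01, k] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_power_bins_masked_to_zero(self):
        coef = np.zeros((3, 12, 257), dtype=complex)
        coef[:, 0, 10] = 1.0  # ROI 1 has no power anywhere
        cs = con.cross_spectra(coef, np.fft.rfftfreq(512, 1 / 200.0))
        ic = con.imaginary_coherence(cs)
        assert np.all(ic == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounded_by_one_on_arbitrary_signals(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        coef = (rng.standard_normal((k, 12, 30))
                + 1j * rng.standard_normal((k, 12, 30)))
        cs = con.cross_spectra(coef, np.linspace(0, 40, 30))
        ic = con.imaginary_coherence(cs)
        assert np.all(np.abs(ic) <= 1.0 + 1e-12)


class TestBandAggregation:
    def test_constant_ic_passes_through(self):
        freqs = np.fft.rfftfreq(512, 1 / 200.0)
        ic = np.full((66, 257), 0.3)
        out = con.band_ic(ic, freqs, spe.BandScheme(iaf=9.5))
        assert np.allclose(out, 0.3)

    def test_symmetric_bins_cancel(self):
        """Signed aggregation: equal and opposite per-bin values average to
        zero - the documented behaviour of the signed mean."""
        freqs = np.fft.rfftfreq(512, 1 / 200.0)
        scheme = spe.BandScheme(iaf=9.5)
        idx = spe.bin_band_indices(freqs, scheme)
        ic = np.zeros((66, 257))
        beta2 = [k for k in range(257) if idx[k] == spe.BAND_ORDER.index("beta2")]
        half = len(beta2) // 2
        ic[:, beta2[:half]] = 0.4
        ic[:, beta2[half:2 * half]] = -0.4
        out = con.band_ic(ic, freqs, scheme)
        assert np.allclose(out[:, spe.BAND_ORDER.index("beta2")], 0.0)

    def test_matches_bruteforce_bin_loop(self):
        rng = np.random.default_rng(5)
        freqs = np.fft.rfftfreq(512, 1 / 200.0)
        ic = rng.uniform(-1, 1, (66, 257))
        scheme = spe.BandScheme(iaf=9.1)
        out = con.band_ic(ic, freqs, scheme)
        idx = spe.bin_band_indices(freqs, scheme)
        for b in range(7):
            bins = [k for k in range(257) if idx[k] == b]
            brute = np.array([np.mean([ic[p, k] for k in bins])
                              for p in range(66)])
            assert np.allclose(out[:, b], brute)


class TestFisherZ:
    def test_known_values(self):
        assert con.fisher_z(0.0) == 0.0
        assert con.fisher_z(0.5) == pytest.approx(0.5493061443340549, rel=1e-12)

    def test_odd_function(self):
        vals = np.linspace(-0.95, 0.95, 21)
        assert np.allclose(con.fisher_z(-vals), -con.fisher_z(vals))

    def test_clipping_keeps_z_finite(self):
        z = con.fisher_z(np.array([1.0, -1.0, 2.0]))
        assert np.all(np.isfinite(z))
        assert z[0] > 13  # atanh(1 - 1e-12)


class TestGroupAverage:
    def test_grand_average_is_subject_mean_of_z(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((5, 66, 7))
        g = con.group_average(z)
        assert np.allclose(g.mean_z, z.mean(axis=0))
        assert g.n_subjects == 5

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            con.group_average(np.zeros((1, 66, 7)))


def test_coupled_cohort_pair_shows_elevated_alpha_connectivity(small_result):
    """The generator's PCC--PCu alpha coupling (stronger in the MCI-like
    group) surfaces as a larger Fisher-z imaginary coherence there."""
    g = np.asarray(small_result.metadata["group"])
    p = pair_index("PCC_L", "PCu_L")
    alpha = [spe.BAND_ORDER.index("alpha1"), spe.BAND_ORDER.index("alpha2")]
    z_mci = small_result.connectivity.z[g == "MCI"][:, p, alpha].mean()
    z_ad = small_result.connectivity.z[g == "AD"][:, p, alpha].mean()
    assert z_mci > z_ad
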
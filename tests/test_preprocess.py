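import numpy as np
import pytest
from scipy import signal as sg

from dmnrest import preprocess as pre
from dmnrest import synth
from dmnrest.montage import CHANNELS_1020


def make_rec(data, fs=200.0, mastoid=None):
    return pre.EEGRecording(data=data, fs=fs, mastoid=mastoid)


@pytest.fixture(scope="module")
def clean_subject(space2, lf2):
    spec = synth.mci_like_spec(n_subjects=2, duration_s=64.0)
    return synth.simulate_subject(spec, space2, lf2, 0)[0]


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self):
        data = np.random.default_rng(0).standard_normal((19, 100))
        rec = make_rec(data, mastoid=np.zeros((2, 100)))
        assert np.array_equal(pre.rereference(rec).data, data)

    def test_channels_equal_to_reference_annihilate(self):
        ref = np.sin(np.linspace(0, 10, 300))
        rec = make_rec(np.tile(ref, (19, 1)), mastoid=np.tile(ref, (2, 1)))
        assert np.allclose(pre.rereference(rec).data, 0.0)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        rec = make_rec(rng.standard_normal((19, 200)),
                       mastoid=rng.standard_normal((2, 200)))
        once = pre.rereference(rec)
        twice = pre.rereference(once)
        assert np.allclose(once.data, twice.data)
        assert once.reference == "linked_mastoid_average"

    def test_missing_mastoid_is_noop(self):
        data = np.random.default_rng(2).standard_normal((19, 100))
        out = pre.rereference(make_rec(data))
        assert np.array_equal(out.data, data)


class TestBandpass:
    def sine(self, f0, dur=20.0, fs=200.0):
        t = np.arange(0, dur, 1 / fs)
        return make_rec(np.tile(np.sin(2 * np.pi * f0 * t), (19, 1)), fs=fs)

    def attenuation_db(self, f0):
        rec = self.sine(f0)
        out = pre.bandpass(rec)
        sl = slice(800, -800)  # avoid edge transients
        ratio = out.data[0, sl].std() / rec.data[0, sl].std()
        return -20 * np.log10(max(ratio, 1e-15))

    def test_passband_preserved(self):
        assert self.attenuation_db(10.0) < 0.45  # within 5% amplitude

    @pytest.mark.parametrize("f0", [60.0, 0.5, 70.0])
    def test_stopband_attenuation(self, f0):
        """Measured response of the implemented zero-phase design."""
        assert self.attenuation_db(f0) >= 40.0

    def test_dc_removed(self):
        rec = make_rec(np.full((19, 2000), 7.0))
        out = pre.bandpass(rec)
        assert abs(out.data[0, 500:-500].mean()) < 0.05

    def test_upper_edge_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pre.bandpass(self.sine(10.0), lo=1.0, hi=100.0)


class TestSegment:
    def test_sixty_seconds_give_thirty_epochs(self):
        rec = make_rec(np.zeros((19, 12000)))
        assert pre.segment(rec).n_epochs == 30

    def test_trailing_remainder_dropped(self):
        rec = make_rec(np.zeros((19, 700)))  # 3.5 s
        assert pre.segment(rec).n_epochs == 1

    def test_concatenation_reproduces_recording(self):
        data = np.random.default_rng(0).standard_normal((19, 1200))
        eset = pre.segment(make_rec(data))
        rebuilt = eset.epochs.transpose(1, 0, 2).reshape(19, -1)
        assert np.array_equal(rebuilt, data)


class TestDecompose:
    def test_two_source_recovery(self):
        """Known-mixing oracle: two independent uniform sources mixed into
        two channels are unmixed up to permutation and scale."""
        rng = np.random.default_rng(0)
        s = rng.uniform(-1, 1, (2, 4000))
        a = np.array([[1.0, 0.6], [-0.4, 1.0]])
        x = (a @ s).reshape(2, 10, 400).transpose(1, 0, 2)
        eset = pre.EpochSet(epochs=x, fs=200.0, channel_labels=("ch0", "ch1"))
        dec = pre.decompose(eset, n_components=2, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([s, dec.activations]))[:2, 2:])
        # each source matches exactly one component
        assert np.all(np.sort(corr, axis=1)[:, -1] >= 0.99)

    def test_full_rank_reconstruction(self, clean_subject):
        eset = pre.segment(pre.bandpass(pre.rereference(clean_subject)))
        dec = pre.decompose(eset, seed=0)
        x = eset.epochs.transpose(1, 0, 2).reshape(19, -1)
        err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
        assert err <= 1e-6

    def test_seed_determinism(self, clean_subject):
        eset = pre.segment(pre.bandpass(pre.rereference(clean_subject)))
        a = pre.decompose(eset, seed=3)
        b = pre.decompose(eset, seed=3)
        assert np.array_equal(a.mixing, b.mixing)

    def test_rank_deficient_input_reduces_components(self):
        one = np.sin(np.linspace(0, 50, 2000))
        x = np.tile(one, (19, 1)).reshape(19, 5, 400).transpose(1, 0, 2)
        eset = pre.EpochSet(epochs=x, fs=200.0)
        dec = pre.decompose(eset, seed=0)
        assert dec.n_components < 19


class TestScoreAndReject:
    def test_clean_subject_keeps_all_components(self, clean_subject):
        eset = pre.segment(pre.bandpass(pre.rereference(clean_subject)))
        dec = pre.decompose(eset, seed=0)
        cleaned, rejected = pre.score_and_reject(dec)
        assert rejected == []
        assert np.allclose(cleaned.epochs, eset.epochs, atol=1e-6)

    def test_injected_ocular_component_flagged(self, clean_subject):
        rec = synth.inject_artifacts(clean_subject, {"ocular"}, seed=1)
        eset = pre.segment(pre.bandpass(pre.rereference(rec)))
        dec = pre.decompose(eset, seed=0)
        _, rejected = pre.score_and_reject(dec)
        assert len(rejected) >= 1
        # the flagged component is the most frontal one
        assert int(np.argmax(dec.frontal_gradient)) in rejected

    def test_injected_muscle_component_flagged(self, clean_subject):
        rec = synth.inject_artifacts(clean_subject, {"muscle"}, seed=1)
        eset = pre.segment(pre.bandpass(pre.rereference(rec)))
        dec = pre.decompose(eset, seed=0)
        _, rejected = pre.score_and_reject(dec)
        assert int(np.argmax(dec.hf_power_ratio)) in rejected

    def test_rejection_restores_frontal_delta_power(self, clean_subject):
        """Efficacy: after removing the ocular component, Fp1 delta power
        returns to within 20% of the artifact-free ground truth."""

        def fp1_delta(eset):
            x = eset.epochs[:, 0, :].ravel()
            f, p = sg.welch(x, fs=200.0, nperseg=512)
            return p[(f >= 1) & (f < 4)].sum()

        clean_eset = pre.segment(pre.bandpass(pre.rereference(clean_subject)))
        rec = synth.inject_artifacts(clean_subject, {"ocular"}, seed=2)
        eset = pre.segment(pre.bandpass(pre.rereference(rec)))
        dec = pre.decompose(eset, seed=0)
        cleaned, rejected = pre.score_and_reject(dec)
        assert rejected
        ref = fp1_delta(clean_eset)
        assert fp1_delta(eset) > 2 * ref          # artifact clearly visible
        assert abs(fp1_delta(cleaned) - ref) <= 0.2 * ref

    def test_refuses_to_reject_everything(self, clean_subject):
        eset = pre.segment(pre.bandpass(pre.rereference(clean_subject)))
        dec = pre.decompose(eset, seed=0)
        thr = pre.RejectionThresholds(frontal_gradient_min=-1.0,
                                      spectral_slope_max=10.0)
        with pytest.raises(ValueError, match="all components"):
            pre.score_and_reject(dec, thresholds=thr)


class TestSelectEpochs:
    @pytest.fixture()
    def eset45(self):
        data = np.arange(45 * 19 * 400, dtype=float).reshape(45, 19, 400)
        return pre.EpochSet(epochs=data, fs=200.0)

    def test_exhaustive_case_preserves_order(self, eset45):
        sub = pre.EpochSet(epochs=eset45.epochs[:30], fs=200.0)
        out = pre.select_epochs(sub, n=30, seed=0)
        assert np.array_equal(out.epochs, sub.epochs)

    def test_subset_unique_and_chronological(self, eset45):
        out = pre.select_epochs(eset45, n=30, seed=1)
        firsts = out.epochs[:, 0, 0]
        assert out.n_epochs == 30
        assert np.all(np.diff(firsts) > 0)      # order preserved, unique

    def test_seeded_selection_reproducible(self, eset45):
        a = pre.select_epochs(eset45, n=30, seed=7)
        b = pre.select_epochs(eset45, n=30, seed=7)
        assert np.array_equal(a.epochs, b.epochs)

    def test_shortfall_reported(self, eset45):
        with pytest.raises(ValueError, match="shortfall"):
            pre.select_epochs(eset45, n=50, seed=0)


def test_matched_groups_reject_similar_component_counts(space1, lf1):
    """Two groups from the same generator (with injected artifacts) should
    not differ systematically in how many components are rejected."""
    counts = {0: [], 1: []}
    for grp, seed in ((0, 11), (1, 22)):
        spec = synth.mci_like_spec(n_subjects=3, duration_s=64.0, seed=seed)
        for i in range(spec.n_subjects):
            rec, _ = synth.simulate_subject(spec, space1, lf1, i)
            rec = synth.inject_artifacts(rec, {"ocular", "muscle"},
                                         seed=100 * grp + i)
            eset = pre.segment(pre.bandpass(pre.rereference(rec)))
            _, rejected = pre.score_and_reject(pre.decompose(eset, seed=i))
            counts[grp].append(len(rejected))
    a, b = np.array(counts[0]), np.array(counts[1])
    assert a.mean() > 0 and b.mean() > 0
    # difference-of-means CI covers zero
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    assert abs(a.mean() - b.mean()) <= max(2.78 * se, 1.0)
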
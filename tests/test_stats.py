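import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from dmnrest import stats as dst


def make_tidy(y, groups, factors):
    """y: (n_subjects, *level_counts) array -> tidy frame."""
    names = list(factors)
    rows = []
    for s in range(y.shape[0]):
        it = np.ndindex(*y.shape[1:])
        for idx in it:
            row = {"subject": f"s{s}", "group": groups[s],
                   "value": y[(s, *idx)]}
            for name, i in zip(names, idx):
                row[name] = f"{name}{i}"
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def random_design():
    rng = np.random.default_rng(0)
    n = 8
    y = rng.standard_normal((2 * n, 3, 4))
    y[:n] += 0.4                      # group shift
    y[:, 1] += 0.6                    # band effect
    y[:n, :, 2] += 0.5                # group x roi interaction
    groups = ["A"] * n + ["B"] * n
    return y, groups


class TestAnovaActivation:
    def test_constant_data_gives_null_group_effect(self):
        y = np.ones((8, 5)) * 3.0
        y += np.arange(5)             # region effect only, no group
        df = make_tidy(y, ["A"] * 4 + ["B"] * 4, ["roi"])
        aov = dst.anova_activation(df, within="roi")
        grp = aov[aov["effect"] == "group"].iloc[0]
        assert grp["F"] == pytest.approx(0.0, abs=1e-20)

    def test_group_f_equals_oneway_on_subject_means(self, random_design):
        """Oracle: in a balanced mixed design the between-groups test is
        the one-way ANOVA on the subject means across regions."""
        y, groups = random_design
        df = make_tidy(y.mean(axis=1), groups, ["roi"])
        aov = dst.anova_activation(df, within="roi")
        grp = aov[aov["effect"] == "group"].iloc[0]
        means = y.mean(axis=(1, 2))
        f_ref, p_ref = sps.f_oneway(means[:8], means[8:])
        assert grp["F"] == pytest.approx(f_ref, rel=1e-9)
        assert grp["p"] == pytest.approx(p_ref, rel=1e-9)


class TestAnovaPower:
    def test_matches_pingouin_on_collapsed_designs(self, random_design):
        """Dual-route check: collapsing one within factor of the balanced
        split-plot reproduces pingouin's two-way mixed ANOVA exactly."""
        y, groups = random_design
        df = make_tidy(y, groups, ["band", "roi"])
        mine = dst.anova_power(df, within=("band", "roi"), correction=False)
        for factor, axis in (("band", 2), ("roi", 1)):
            coll = make_tidy(y.mean(axis=axis), groups, [factor])
            ref = pg.mixed_anova(data=coll, dv="value", within=factor,
                                 subject="subject", between="group")
            for eff_mine, eff_ref in ((factor, factor),
                                      (f"group*{factor}", "Interaction"),
                                      ("group", "group")):
                f_mine = float(mine.loc[mine["effect"] == eff_mine, "F"].iloc[0])
                f_ref = float(ref.loc[ref["Source"] == eff_ref, "F"].iloc[0])
                assert f_mine == pytest.approx(f_ref, rel=1e-9), eff_mine

    def test_null_data_flags_nothing(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((12, 3, 4)) * 0.0 + 5.0
        df = make_tidy(y, ["A"] * 6 + ["B"] * 6, ["band", "roi"])
        aov = dst.anova_power(df, correction=False)
        assert np.all(aov["p"].fillna(1.0) >= 0.99)

    def test_permuted_labels_calibrated(self):
        """Group-involving effects under a shuffled-label null are
        significant about alpha of the time."""
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            y = rng.standard_normal((10, 2, 3))
            df = make_tidy(y, ["A"] * 5 + ["B"] * 5, ["band", "roi"])
            aov = dst.anova_power(df, correction=False)
            p = float(aov.loc[aov["effect"] == "group", "p"].iloc[0])
            hits += p < 0.05
        assert sps.binomtest(hits, n_rep, 0.05).pvalue > 1e-3

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((5, 2, 2))
        df = make_tidy(y, ["A"] * 3 + ["B"] * 2, ["band", "roi"])
        with pytest.raises(ValueError, match="balanced"):
            dst.anova_power(df)

    def test_gg_correction_weakens_p_under_nonsphericity(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((12, 1, 1))
        y = np.concatenate([base + 0.1 * rng.standard_normal((12, 1, 1))
                            for _ in range(4)], axis=1)   # correlated levels
        y = np.repeat(y, 2, axis=2)
        y += 0.3 * np.arange(4)[None, :, None]
        df = make_tidy(y, ["A"] * 6 + ["B"] * 6, ["band", "roi"])
        aov = dst.anova_power(df, correction=True)
        band = aov[aov["effect"] == "band"].iloc[0]
        assert band["eps"] < 1.0
        assert band["p_gg"] >= band["p"]


class TestPosthoc:
    def test_injected_ordering_recovered(self):
        rng = np.random.default_rng(5)
        levels = {"alpha1": 3.0, "theta": 2.0, "delta": 1.0}
        rows = []
        for s in range(12):
            for band, mu in levels.items():
                rows.append({"subject": f"s{s}", "band": band,
                             "value": mu + 0.2 * rng.standard_normal()})
        ph = dst.pairwise_bonferroni(pd.DataFrame(rows), factor="band")
        sig = ph[ph["p_bonf"] < 0.05]
        assert len(sig) == 3
        means = {b: mu for b, mu in levels.items()}
        for _, row in sig.iterrows():
            assert np.sign(row["mean_diff"]) == np.sign(
                means[row["level_a"]] - means[row["level_b"]])


class TestCorrections:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 5, 0.05), (0.5, 10, 1.0), (0.2, 1, 0.2)])
    def test_bonferroni_arithmetic(self, p, m, expected):
        assert dst.bonferroni([p], m=m)[0] == pytest.approx(expected)

    def test_bh_steps_up_the_ladder(self):
        """p = {0.01..0.05} at q = 0.05: every rank i satisfies
        p_(i) <= i q / m, so all five are rejected."""
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        adj, mask = dst.fdr_bh(p, q=0.05)
        assert mask.all()
        assert np.allclose(adj, 0.05)

    def test_all_zero_pvalues_rejected(self):
        adj, mask = dst.fdr_bh(np.zeros(10))
        assert mask.all() and np.all(adj == 0)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 100)
        adj, _ = dst.fdr_bh(p)
        assert np.all(adj >= p - 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dst.fdr_bh(np.array([0.5, 1.5]))


class TestConnectivityContrasts:
    def test_injected_difference_detected_with_sign(self):
        rng = np.random.default_rng(7)
        z_a = 0.05 * rng.standard_normal((21, 66, 7))
        z_b = 0.05 * rng.standard_normal((21, 66, 7))
        z_a[:, 10, 3] += 0.4
        out = dst.connectivity_contrasts(z_a, z_b)
        assert len(out) == 462
        hit = out[(out["pair"] == dst.PAIR_LABELS[10])
                  & (out["band"] == dst.BAND_ORDER[3])].iloc[0]
        assert hit["significant"]
        assert hit["direction"] == 1
        assert out["significant"].sum() <= 5

    def test_injected_coupling_survives_fdr_with_correct_sign(self):
        """A strength-1 lagged coupling present in only one group is found
        in the 462-test FDR mask (right cell, right direction) in >= 80%
        of replicate cohorts at n = 21/group."""
        from dmnrest import studies
        rate = studies.connectivity_power_study(n_replicates=10,
                                                n_per_group=21, seed=4)
        assert rate >= 0.8

    def test_identical_groups_rarely_reject(self):
        rng = np.random.default_rng(8)
        z = 0.05 * rng.standard_normal((42, 66, 7))
        out = dst.connectivity_contrasts(z[:21], z[21:])
        assert out["significant"].sum() <= 2


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = dst.pearson_mmse(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(9)
        r, _ = dst.pearson_mmse(rng.standard_normal(2000),
                                rng.standard_normal(2000))
        assert abs(r) < 0.08

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            dst.pearson_mmse([1.0, 2.0], [1.0, 2.0])

    def test_correlation_tables_cover_the_grid(self):
        rng = np.random.default_rng(10)
        vals = rng.standard_normal((12, 12, 7))
        z = rng.standard_normal((12, 66, 7))
        mmse = rng.integers(5, 30, 12).astype(float)
        assert len(dst.power_mmse_correlations(vals, mmse)) == 84
        assert len(dst.connectivity_mmse_correlations(z, mmse)) == 462


def test_cohort_mmse_correlates_with_posterior_alpha(small_result):
    """Pooled over both groups, MMSE correlates positively with posterior
    alpha power and negatively with posterior theta (the generator links
    MMSE to alpha amplitude and the groups differ in both directions)."""
    from dmnrest.montage import POSTERIOR_ROIS, ROI_ORDER
    from dmnrest.spectral import BAND_ORDER
    bp = small_result.band_power.values
    mmse = np.asarray(small_result.metadata["mmse"], dtype=float)
    post = [ROI_ORDER.index(r) for r in POSTERIOR_ROIS]
    r_alpha, _ = dst.pearson_mmse(
        bp[:, post, BAND_ORDER.index("alpha2")].mean(axis=1), mmse)
    r_theta, _ = dst.pearson_mmse(
        bp[:, post, BAND_ORDER.index("theta")].mean(axis=1), mmse)
    assert r_alpha > 0
    assert r_theta < 0
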
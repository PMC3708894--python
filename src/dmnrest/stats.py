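"""Group statistics: mixed ANOVAs, Bonferroni post-hocs, FDR-corrected
connectivity contrasts, and Pearson correlations with the cognitive score.

The two-way mixed ANOVA (Group between, Region within) is delegated to
pingouin; the three-way design (Group x Band x Region, Band and Region
repeated) is a balanced split-plot computed here, with Greenhouse-Geisser
sphericity correction per within-subject error stratum (applied by
default, toggleable).  The 66 ROI pairs x 7 bands = 462 connectivity
contrasts are two-sample t-tests on per-subject Fisher-z values, corrected
by Benjamini-Hochberg FDR; the sign of each contrast is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import BAND_ORDER, PAIR_LABELS
from .montage import ROI_ORDER


@dataclass
class StatsReport:
    """Bundle of the statistical outputs of one pipeline run."""

    anova_activation: pd.DataFrame | None = None
    anova_power: pd.DataFrame | None = None
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    connectivity_contrasts: pd.DataFrame | None = None
    power_correlations: pd.DataFrame | None = None
    connectivity_correlations: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# ANOVA

def anova_activation(df: pd.DataFrame, dv: str = "value", subject: str = "subject",
                     between: str = "group", within: str = "roi",
                     correction: bool = True) -> pd.DataFrame:
    """Two-way mixed ANOVA (Group between-subjects, Region repeated).

    ``df`` is tidy with one row per subject x region.  Returns a table
    with effect, F, df1, df2, p (and sphericity-corrected p where
    applicable).
    """
    try:
        aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                             between=between, correction=correction)
    except KeyError:
        # degenerate (e.g. constant-residual) data defeat pingouin's
        # internals; fall back to the plain balanced split-plot
        return _splitplot_2way(df, dv=dv, subject=subject, between=between,
                               within=within)
    out = pd.DataFrame({
        "effect": aov["Source"],
        "F": aov["F"],
        "df1": aov["DF1"],
        "df2": aov["DF2"],
        "p": aov["p_unc"],
    })
    if "p_GG_corr" in aov:
        out["p_gg"] = aov["p_GG_corr"]
    # degenerate strata (constant data) produce 0/0: report F = 0, p = 1
    null_eff = out["F"].isna() & (aov["SS"].to_numpy() == 0)
    out.loc[null_eff, "F"] = 0.0
    out.loc[null_eff, "p"] = 1.0
    return out


def _splitplot_2way(df: pd.DataFrame, dv: str, subject: str, between: str,
                    within: str) -> pd.DataFrame:
    """Balanced two-way mixed ANOVA by direct sums of squares (used only
    when pingouin cannot process the data); 0/0 strata report F=0, p=1."""
    piv = df.pivot_table(index=[between, subject], columns=within, values=dv,
                         aggfunc="mean")
    counts = piv.groupby(level=0).size()
    if counts.nunique() != 1:
        raise ValueError("balanced design required: equal subjects per group")
    g, n, a = len(counts), int(counts.iloc[0]), piv.shape[1]
    y = piv.to_numpy().reshape(g, n, a)
    gm = y.mean()
    m_g, m_s, m_i, m_gi = (y.mean(axis=(1, 2)), y.mean(axis=2),
                           y.mean(axis=(0, 1)), y.mean(axis=1))
    ss_group = n * a * np.sum((m_g - gm) ** 2)
    ss_subj = a * np.sum((m_s - m_g[:, None]) ** 2)
    ss_w = g * n * np.sum((m_i - gm) ** 2)
    ss_gw = n * np.sum((m_gi - m_g[:, None] - m_i[None, :] + gm) ** 2)
    ss_err = np.sum((y - m_s[:, :, None] - m_gi[:, None, :]
                     + m_g[:, None, None]) ** 2)
    rows = []
    for name, ss, df1, ss_e, df2 in (
            (between, ss_group, g - 1, ss_subj, g * (n - 1)),
            (within, ss_w, a - 1, ss_err, g * (n - 1) * (a - 1)),
            ("Interaction", ss_gw, (g - 1) * (a - 1), ss_err,
             g * (n - 1) * (a - 1))):
        ms, ms_e = ss / df1, ss_e / df2
        f_val = ms / ms_e if ms_e > 0 else (np.inf if ms > 0 else 0.0)
        rows.append({"effect": name, "F": f_val, "df1": df1, "df2": df2,
                     "p": float(sps.f.sf(f_val, df1, df2))})
    return pd.DataFrame(rows)


def _gg_epsilon(d: np.ndarray, groups: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from pooled within-group covariance."""
    resid = d - np.vstack([d[groups == g].mean(axis=0)
                           for g in groups])  # subject minus its group mean
    n_g = len(np.unique(groups))
    s = resid.T @ resid / (d.shape[0] - n_g)
    m = contrast @ s @ contrast.T
    dd = contrast.shape[0]
    tr, tr2 = np.trace(m), np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    eps = tr ** 2 / (dd * tr2)
    return float(np.clip(eps, 1.0 / dd, 1.0))


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (orthogonal complement of the mean)."""
    h = np.eye(k) - np.ones((k, k)) / k
    u, sv, _ = np.linalg.svd(h)
    return u[:, :k - 1].T


def anova_power(df: pd.DataFrame, dv: str = "value", subject: str = "subject",
                between: str = "group", within: tuple[str, str] = ("band", "roi"),
                correction: bool = True) -> pd.DataFrame:
    """Three-way mixed ANOVA: Group (between) x Band x Region (repeated).

    Balanced split-plot decomposition; requires every subject to have all
    band x region cells and equal group sizes.  Each within-subject effect
    is tested against its own Subject-interaction error stratum, with
    optional Greenhouse-Geisser correction.
    """
    w1, w2 = within
    lev_g = sorted(df[between].unique())
    lev_a = sorted(df[w1].unique())
    lev_b = sorted(df[w2].unique())
    piv = df.pivot_table(index=[between, subject], columns=[w1, w2],
                         values=dv, aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("design must be complete (every subject x cell)")
    counts = piv.groupby(level=0).size()
    if counts.nunique() != 1:
        raise ValueError("balanced design required: equal subjects per group")
    n = int(counts.iloc[0])
    g, a, b = len(lev_g), len(lev_a), len(lev_b)
    cols = pd.MultiIndex.from_product([lev_a, lev_b])
    y = piv[cols].to_numpy().reshape(g, n, a, b)

    gm = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_s = y.mean(axis=(2, 3))                       # (g, n)
    m_i = y.mean(axis=(0, 1, 3))
    m_j = y.mean(axis=(0, 1, 2))
    m_gi = y.mean(axis=(1, 3))
    m_gj = y.mean(axis=(1, 2))
    m_ij = y.mean(axis=(0, 1))
    m_si = y.mean(axis=3)                           # (g, n, a)
    m_sj = y.mean(axis=2)                           # (g, n, b)
    m_gij = y.mean(axis=1)                          # (g, a, b)

    ss_group = n * a * b * np.sum((m_g - gm) ** 2)
    ss_subj = a * b * np.sum((m_s - m_g[:, None]) ** 2)
    ss_w1 = g * n * b * np.sum((m_i - gm) ** 2)
    ss_gw1 = n * b * np.sum((m_gi - m_g[:, None] - m_i[None, :] + gm) ** 2)
    ss_e1 = b * np.sum((m_si - m_s[:, :, None] - m_gi[:, None, :]
                        + m_g[:, None, None]) ** 2)
    ss_w2 = g * n * a * np.sum((m_j - gm) ** 2)
    ss_gw2 = n * a * np.sum((m_gj - m_g[:, None] - m_j[None, :] + gm) ** 2)
    ss_e2 = a * np.sum((m_sj - m_s[:, :, None] - m_gj[:, None, :]
                        + m_g[:, None, None]) ** 2)
    ss_w12 = g * n * np.sum((m_ij - m_i[:, None] - m_j[None, :] + gm) ** 2)
    ss_gw12 = n * np.sum((m_gij - m_gi[:, :, None] - m_gj[:, None, :]
                          - m_ij[None, :, :] + m_g[:, None, None]
                          + m_i[None, :, None] + m_j[None, None, :] - gm) ** 2)
    resid = (y - m_si[:, :, :, None] - m_sj[:, :, None, :]
             - m_gij[:, None, :, :] + m_s[:, :, None, None]
             + m_gi[:, None, :, None] + m_gj[:, None, None, :]
             - m_g[:, None, None, None])
    ss_e3 = np.sum(resid ** 2)

    df_e1, df_e2 = g * (n - 1) * (a - 1), g * (n - 1) * (b - 1)
    df_e3 = g * (n - 1) * (a - 1) * (b - 1)
    rows = [
        (between, ss_group, g - 1, ss_subj, g * (n - 1), None),
        (w1, ss_w1, a - 1, ss_e1, df_e1, "w1"),
        (f"{between}*{w1}", ss_gw1, (g - 1) * (a - 1), ss_e1, df_e1, "w1"),
        (w2, ss_w2, b - 1, ss_e2, df_e2, "w2"),
        (f"{between}*{w2}", ss_gw2, (g - 1) * (b - 1), ss_e2, df_e2, "w2"),
        (f"{w1}*{w2}", ss_w12, (a - 1) * (b - 1), ss_e3, df_e3, "w12"),
        (f"{between}*{w1}*{w2}", ss_gw12, (g - 1) * (a - 1) * (b - 1),
         ss_e3, df_e3, "w12"),
    ]

    eps = {"w1": 1.0, "w2": 1.0, "w12": 1.0}
    if correction:
        groups_flat = np.repeat(np.arange(g), n)
        d1 = y.mean(axis=3).reshape(g * n, a)
        d2 = y.mean(axis=2).reshape(g * n, b)
        d12 = y.reshape(g * n, a * b)
        c1 = _orthonormal_contrast(a)
        c2 = _orthonormal_contrast(b)
        eps["w1"] = _gg_epsilon(d1, groups_flat, c1)
        eps["w2"] = _gg_epsilon(d2, groups_flat, c2)
        eps["w12"] = _gg_epsilon(d12, groups_flat, np.kron(c1, c2))

    out = []
    for name, ss, df1, ss_err, df2, stratum in rows:
        ms, ms_err = ss / df1, ss_err / df2
        if ms_err > 0:
            f_val = ms / ms_err
        else:
            # 0/0 (e.g. constant data): no evidence of an effect
            f_val = np.inf if ms > 0 else 0.0
        p = float(sps.f.sf(f_val, df1, df2))
        row = {"effect": name, "SS": ss, "df1": df1, "df2": df2,
               "F": f_val, "p": p}
        if correction and stratum is not None:
            e = eps[stratum]
            row["eps"] = e
            row["p_gg"] = float(sps.f.sf(f_val, df1 * e, df2 * e))
        out.append(row)
    return pd.DataFrame(out)


def pairwise_bonferroni(df: pd.DataFrame, dv: str = "value",
                        subject: str = "subject", factor: str = "band",
                        ) -> pd.DataFrame:
    """Post-hoc paired t-tests between all levels of a repeated factor,
    Bonferroni-adjusted over the number of contrasts."""
    piv = df.pivot_table(index=subject, columns=factor, values=dv,
                         aggfunc="mean")
    levels = list(piv.columns)
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in combinations(levels, 2):
        t, p = sps.ttest_rel(piv[a], piv[b])
        rows.append({"level_a": a, "level_b": b,
                     "mean_diff": float(piv[a].mean() - piv[b].mean()),
                     "t": float(t), "p": float(p),
                     "p_bonf": float(min(1.0, m * p))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple-comparison corrections

def bonferroni(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m p)."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (adjusted p, rejection mask at q)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# contrasts and correlations

def connectivity_contrasts(z_a: np.ndarray, z_b: np.ndarray,
                           group_names: tuple[str, str] = ("AD", "MCI"),
                           q: float = 0.05) -> pd.DataFrame:
    """Two-sample t-tests on Fisher-z connectivity, one per (pair, band).

    ``z_a``/``z_b``: (n_subjects, 66, 7).  The 462 raw p-values are
    FDR-corrected together; ``direction`` is +1 where the first group's
    mean z is larger.
    """
    z_a, z_b = np.asarray(z_a), np.asarray(z_b)
    t, p = sps.ttest_ind(z_a, z_b, axis=0)
    diff = z_a.mean(axis=0) - z_b.mean(axis=0)
    p_adj, reject = fdr_bh(p.ravel(), q=q)
    rows = []
    flat = 0
    for i, pair in enumerate(PAIR_LABELS):
        for j, band in enumerate(BAND_ORDER):
            rows.append({"pair": pair, "band": band,
                         "mean_z_" + group_names[0]: float(z_a[:, i, j].mean()),
                         "mean_z_" + group_names[1]: float(z_b[:, i, j].mean()),
                         "diff": float(diff[i, j]),
                         "direction": int(np.sign(diff[i, j])),
                         "t": float(t[i, j]), "p": float(p[i, j]),
                         "p_fdr": float(p_adj[flat]),
                         "significant": bool(reject[flat])})
            flat += 1
    return pd.DataFrame(rows)


def pearson_mmse(values: np.ndarray, mmse: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p."""
    v = np.asarray(values, dtype=float)
    m = np.asarray(mmse, dtype=float)
    if v.size != m.size or v.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(m))):
        raise ValueError("observations must be finite")
    r, p = sps.pearsonr(v, m)
    return float(r), float(p)


def power_mmse_correlations(values: np.ndarray, mmse: np.ndarray) -> pd.DataFrame:
    """ROI x band grid of correlations between normalized power and MMSE.

    ``values``: (n_subjects, 12, 7), pooled over both groups (the
    correlation spans the full MMSE range).
    """
    rows = []
    for i, roi in enumerate(ROI_ORDER):
        for j, band in enumerate(BAND_ORDER):
            r, p = pearson_mmse(values[:, i, j], mmse)
            rows.append({"roi": roi, "band": band, "r": r, "p": p})
    return pd.DataFrame(rows)


def connectivity_mmse_correlations(z: np.ndarray, mmse: np.ndarray) -> pd.DataFrame:
    """Pair x band correlations between Fisher-z connectivity and MMSE."""
    rows = []
    for i, pair in enumerate(PAIR_LABELS):
        for j, band in enumerate(BAND_ORDER):
            r, p = pearson_mmse(z[:, i, j], mmse)
            rows.append({"pair": pair, "band": band, "r": r, "p": p})
    return pd.DataFrame(rows)
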
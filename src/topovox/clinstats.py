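"""Cohort-comparison statistics and the edema index.

Group comparisons follow standard clinical-table conventions: categorical
variables by Pearson's chi-square (no continuity correction) or Fisher's
exact test when expected counts fall below 5; continuous variables by
Welch's t-test when both groups pass Shapiro-Wilk normality, otherwise the
Mann-Whitney U test with tie-corrected normal approximation.  The edema
index (V_tumor + V_edema) / V_tumor quantifies peritumoral edema extent
relative to tumor volume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def pearson_chi_square(table) -> tuple:
    """Pearson chi-square on an r×c contingency table (no Yates correction).

    Returns (chi2, df, p) with χ² = Σ(O−E)²/E, E = row·col/N and
    df = (r−1)(c−1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero marginal")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (hypergeometric enumeration)."""
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    _, p = sps.fisher_exact(obs, alternative="two-sided")
    return float(p)


def mann_whitney_u(x, y) -> tuple:
    """Mann-Whitney U with tie-corrected normal approximation: (U, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def t_test(x, y) -> tuple:
    """Welch's (unequal-variance) two-sample t-test: (t, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x) -> tuple:
    """Shapiro-Wilk normality test (thin wrapper): (W, p)."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def edema_index(v_tumor: float, v_edema: float) -> float:
    """(V_tumor + V_edema) / V_tumor; >= 1, equal to 1 when no edema."""
    if v_tumor <= 0:
        raise ValueError("tumor volume must be positive")
    if v_edema < 0:
        raise ValueError("edema volume must be nonnegative")
    return (v_tumor + v_edema) / v_tumor


def _fmt_continuous(x):
    x = np.asarray(x, float)
    return {
        "mean_sd": f"{x.mean():.2f} ({x.std(ddof=1):.2f})",
        "median_iqr": f"{np.median(x):.2f} [{np.percentile(x, 25):.2f}, "
                      f"{np.percentile(x, 75):.2f}]",
    }


def cohort_summary(table: pd.DataFrame, grouping: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Clinical-table style group comparison of every other column.

    Continuous variables: Shapiro-Wilk routes to Welch's t-test (both groups
    normal) or Mann-Whitney; reported as mean (SD) and median [IQR].
    Categorical variables: counts (%) per level, chi-square unless any
    expected count < 5 and the table is 2×2, then Fisher.  Constant
    variables are summarized with the p-value omitted.
    """
    groups = table[grouping]
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    rows = []
    for col in table.columns:
        if col == grouping:
            continue
        series = table[col]
        g0 = series[groups == levels[0]].dropna()
        g1 = series[groups == levels[1]].dropna()
        if pd.api.types.is_numeric_dtype(series):
            if series.dropna().nunique() <= 1:
                rows.append({"variable": col, "type": "continuous",
                             "test": None, "p": None,
                             "group0": _fmt_continuous(g0)["median_iqr"],
                             "group1": _fmt_continuous(g1)["median_iqr"]})
                continue
            normal = (shapiro_wilk(g0)[1] > alpha and shapiro_wilk(g1)[1] > alpha
                      if min(len(g0), len(g1)) >= 3 else False)
            if normal:
                _, p = t_test(g0, g1)
                test = "t"
                f0, f1 = _fmt_continuous(g0)["mean_sd"], _fmt_continuous(g1)["mean_sd"]
            else:
                _, p = mann_whitney_u(g0, g1)
                test = "mann-whitney"
                f0 = _fmt_continuous(g0)["median_iqr"]
                f1 = _fmt_continuous(g1)["median_iqr"]
            rows.append({"variable": col, "type": "continuous", "test": test,
                         "p": p, "group0": f0, "group1": f1})
        else:
            ct = pd.crosstab(series, groups).reindex(columns=levels, fill_value=0)
            def fmt(level):
                c = ct[level]
                tot = c.sum()
                return "; ".join(f"{ix}: {v} ({100 * v / tot:.1f}%)"
                                 for ix, v in c.items())
            if ct.shape[0] < 2 or (ct.sum(axis=1) == 0).any():
                rows.append({"variable": col, "type": "categorical",
                             "test": None, "p": None,
                             "group0": fmt(levels[0]), "group1": fmt(levels[1])})
                continue
            expected = np.outer(ct.sum(axis=1), ct.sum(axis=0)) / ct.values.sum()
            if (expected < 5).any() and ct.shape == (2, 2):
                p = fisher_exact_2x2(ct.values)
                test = "fisher"
            else:
                _, _, p = pearson_chi_square(ct.values)
                test = "chi2"
            rows.append({"variable": col, "type": "categorical", "test": test,
                         "p": p, "group0": fmt(levels[0]), "group1": fmt(levels[1])})
    return pd.DataFrame(rows)
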
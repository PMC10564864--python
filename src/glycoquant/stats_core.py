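"""Transformations and descriptive statistics for the cohort analysis.

The continuous plaque measurements (percent stained area, plaque size) are
right-skewed, so effect sizes are reported per 1-SD increment after a
rank-based inverse normal transform (IRNT).  Other skewed covariates are
natural-log transformed when sample skewness exceeds a threshold.
Baseline tables summarize continuous variables as mean (SD) or median (IQR)
and categoricals as n/N (%), with Wilcoxon rank-sum, chi-square, or Fisher
exact group tests as appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri


@dataclass
class TransformedVector:
    values: np.ndarray
    n_nonmissing: int
    method: str  # irnt | natural_log | identity


def irnt(values, offset: float = 3.0 / 8.0) -> TransformedVector:
    """Rank-based inverse normal transform with the Blom offset.

    Non-missing values are ranked with average ranks for ties and mapped to
    Φ⁻¹((rank − 3/8) / (n + 1/4)), giving an approximately standard-normal
    vector in SD units; missing entries propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("irnt needs at least 3 non-missing values")
    ranks = stats.rankdata(x[obs], method="average")
    out = np.full(x.shape, np.nan)
    out[obs] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return TransformedVector(values=out, n_nonmissing=n, method="irnt")


def irnt_values(values) -> np.ndarray:
    """Convenience wrapper returning only the transformed array."""
    return irnt(values).values


def log_if_skewed(values, skew_threshold: float = 1.0) -> TransformedVector:
    """Natural-log transform applied iff sample skewness exceeds the threshold."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    skew = stats.skew(x[obs], bias=False)
    if skew <= skew_threshold:
        return TransformedVector(values=x.copy(), n_nonmissing=n, method="identity")
    if np.any(x[obs] <= 0):
        raise ValueError("log transform requires strictly positive values")
    out = np.where(obs, np.log(np.where(obs, x, 1.0)), np.nan)
    return TransformedVector(values=out, n_nonmissing=n, method="natural_log")


def _continuous_row(x: pd.Series, groups: list[pd.Series], skew_threshold: float):
    vals = x.dropna().to_numpy(dtype=float)
    skewed = vals.size >= 3 and abs(stats.skew(vals, bias=False)) > skew_threshold
    summaries = []
    for g in groups:
        v = g.dropna().to_numpy(dtype=float)
        if v.size == 0:
            summaries.append("—")
        elif skewed:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            summaries.append(f"{med:.2f} ({q1:.2f}, {q3:.2f})")
        else:
            summaries.append(f"{v.mean():.2f} ({v.std(ddof=1):.2f})")
    a, b = (g.dropna().to_numpy(dtype=float) for g in groups[:2])
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return summaries, p, "Wilcoxon rank sum test"


def _categorical_row(x: pd.Series, group: pd.Series):
    tab = pd.crosstab(x, group)
    chi2, p, dof, expected = stats.chi2_contingency(tab)
    test = "Pearson's Chi-squared test"
    if (expected < 5).any() and tab.shape == (2, 2):
        p = stats.fisher_exact(tab.to_numpy()).pvalue
        test = "Fisher's exact test"
    summaries = []
    for col in tab.columns:
        n_col = tab[col].sum()
        parts = [f"{lvl}: {tab.loc[lvl, col]}/{n_col} ({100 * tab.loc[lvl, col] / n_col:.0f}%)"
                 for lvl in tab.index]
        summaries.append("; ".join(parts))
    return summaries, p, test


def descriptive_table(
    cohort: pd.DataFrame,
    group: str,
    variables: list[str] | None = None,
    skew_threshold: float = 1.0,
) -> pd.DataFrame:
    """Baseline-characteristics table with per-variable group tests.

    Continuous variables are summarized mean (SD), or median (IQR) when
    skewed, and compared across the two group levels by Wilcoxon rank-sum;
    categorical variables are summarized n/N (%) and compared by chi-square,
    falling back to Fisher's exact test for 2×2 tables with any expected
    cell below 5.
    """
    if group not in cohort.columns:
        raise ValueError(f"unknown group column {group!r}")
    levels = [lvl for lvl in cohort[group].dropna().unique()]
    if len(levels) < 2:
        raise ValueError("group must have at least two non-empty levels")
    if variables is None:
        variables = [c for c in cohort.columns if c != group]
    rows = []
    for var in variables:
        x = cohort[var]
        sub = [x[cohort[group] == lvl] for lvl in levels]
        if any(s.dropna().empty for s in sub):
            raise ValueError(f"empty group level for variable {var!r}")
        if pd.api.types.is_numeric_dtype(x) and x.dropna().nunique() > 2:
            summaries, p, test = _continuous_row(x, sub, skew_threshold)
        else:
            summaries, p, test = _categorical_row(x, cohort[group])
        row = {"variable": var, "p_value": p, "test": test}
        row.update({f"summary_{lvl}": s for lvl, s in zip(levels, summaries)})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(values, labels, mode: str = "kruskal") -> dict:
    """Group comparisons of a continuous measurement.

    ``kruskal`` runs a tie-corrected Kruskal–Wallis test across all groups
    (the IPH present/absent contrast); ``pairwise_wilcoxon`` runs Wilcoxon
    rank-sum tests for every pair of groups (the three-level plaque
    phenotype contrast).  Returns group medians along with statistics and
    p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups = {}
    for lvl in pd.unique(labels):
        groups[lvl] = values[labels == lvl]
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    medians = {lvl: float(np.median(v)) for lvl, v in groups.items()}
    if mode == "kruskal":
        if np.ptp(values) == 0:  # all observations identical: no evidence of shift
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups.values())
        return {"mode": mode, "statistic": float(stat), "p_value": float(p),
                "medians": medians}
    if mode == "pairwise_wilcoxon":
        pairwise = {}
        for a, b in combinations(groups, 2):
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            pairwise[(a, b)] = {"statistic": float(res.statistic),
                                "p_value": float(res.pvalue)}
        return {"mode": mode, "pairwise": pairwise, "medians": medians}
    raise ValueError("mode must be 'kruskal' or 'pairwise_wilcoxon'")
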
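"""Statistical comparison of gene-class value distributions.

Pairwise Wilcoxon rank-sum tests (exact for small samples without ties,
normal approximation with tie and continuity corrections otherwise) with
Bonferroni adjustment over the tested family, plus generic two-sided Fisher
exact and Pearson chi-square helpers for 2x2 contingency comparisons.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError

EXACT_N_MAX = 20


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_a + n_b <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.  Returns
    (U statistic of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise UsageError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_compare(
    groups: dict[str, np.ndarray], family: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Wilcoxon rank-sum over a family of group pairs with Bonferroni control.

    ``family`` defaults to all unordered pairs.  Missing values are dropped
    per group; medians and per-group n are reported alongside raw and
    adjusted p-values.
    """
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    if family is None:
        family = list(itertools.combinations(sorted(groups), 2))
    for g1, g2 in family:
        for g in (g1, g2):
            if g not in groups:
                raise UsageError(f"unknown group {g!r}")
    m = len(family)
    rows = []
    for g1, g2 in family:
        a = np.asarray(groups[g1], dtype=float)
        b = np.asarray(groups[g2], dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "median1": float(np.median(a)),
                "median2": float(np.median(b)),
                "n1": len(a),
                "n2": len(b),
                "statistic": stat,
                "p": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    p sums hypergeometric probabilities <= that of the observed table.  The
    odds ratio uses the Haldane half-count correction when a zero cell is
    present (the correction affects the reported ratio only, not p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise UsageError("need a 2x2 table of non-negative integers")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b, c, d = t.ravel()
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table, no continuity correction by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise UsageError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise UsageError("zero marginal total")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def class_distributions(
    values: pd.DataFrame, sets: dict[str, set], metric: str
) -> dict[str, np.ndarray]:
    """Per-class value arrays for one metric from a gene-indexed table."""
    if metric not in values.columns:
        raise UsageError(f"unknown metric {metric!r}")
    v = values.set_index("gene")[metric] if "gene" in values.columns else values[metric]
    return {
        name: v.loc[v.index.intersection(list(members))].to_numpy(dtype=float)
        for name, members in sets.items()
        if members
    }
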
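"""Expression-architecture indices: tissue specificity (tau), expression
variability (CVE) and plasticity (pi).

tau is computed on per-tissue mean TMM-normalized log2 cpm, floored at 0 and
normalized by the maximal component: tau = sum(1 - x_i) / (N - 1), so 1 means
single-tissue expression and 0 ubiquitous expression.  CVE is the coefficient
of variation (sample sd / mean) of normalized cpm across samples.  pi is the
mean |log2FC| over the three control-vs-stress contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .de import compute_tmm_factors, cpm
from .errors import UsageError


def tau(profile) -> float:
    """Tissue-specificity index of one non-negative expression profile.

    The profile is normalized by its maximum; an all-zero profile has no
    defined tau and yields NaN with a warning.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise UsageError("tau needs a 1-D profile over >= 2 contexts")
    if np.any(x < 0):
        raise UsageError("tau is defined on non-negative profiles")
    m = x.max()
    if m == 0:
        warnings.warn("all-zero profile: tau undefined", stacklevel=2)
        return float("nan")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def expression_profiles(
    cm: CountMatrix, context_key: str = "tissue", factors: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene context means of TMM-normalized log2 cpm, floored at 0.

    Replicates are averaged within each context on the log2 cpm scale before
    flooring; the result is the profile matrix tau operates on.
    """
    if factors is None:
        factors = compute_tmm_factors(cm)
    with np.errstate(divide="ignore"):
        logcpm = np.log2(cpm(cm.counts, factors))
    groups = cm.groups(context_key)
    prof = pd.DataFrame(
        {ctx: logcpm[ids].mean(axis=1) for ctx, ids in groups.items()},
        index=cm.gene_ids,
    )
    return prof.clip(lower=0.0).replace(-np.inf, 0.0)


def tau_table(cm: CountMatrix, context_key: str = "tissue") -> pd.Series:
    """tau per gene from a multi-tissue count matrix."""
    prof = expression_profiles(cm, context_key)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prof.apply(lambda row: tau(row.to_numpy()), axis=1).rename("tau")


def cve(cm: CountMatrix, sample_subset=None) -> pd.Series:
    """Coefficient of variation of TMM-normalized cpm across samples.

    Uses the sample (n-1) standard deviation; genes with zero mean get NaN.
    """
    sub = cm if sample_subset is None else cm.subset_samples(sample_subset)
    if sub.shape[1] < 2:
        raise UsageError("CVE needs at least 2 samples")
    factors = compute_tmm_factors(sub)
    c = cpm(sub.counts, factors)
    mean = c.mean(axis=1)
    sd = c.std(axis=1, ddof=1)
    out = sd / mean
    out[mean == 0] = np.nan
    return out.rename("cve")


def plasticity_pi(de_runs: list[pd.DataFrame], variant: str = "mean_abs_fc") -> pd.Series:
    """Plasticity index per gene from per-stage control-vs-stress DE results.

    ``mean_abs_fc`` (default): mean |log2FC| over the runs.  ``de_count``:
    the number of runs in which the gene is significant (FDR < 0.05 and
    |log2FC| > 1).  Genes missing (or filtered) in any run get NaN.
    """
    if not de_runs:
        raise UsageError("no DE runs provided")
    frames = []
    for i, run in enumerate(de_runs):
        r = run.set_index("gene")
        frames.append(r["log2fc"].rename(f"fc{i}").to_frame().join(r["fdr"].rename(f"q{i}")))
    joined = frames[0].join(frames[1:], how="outer")
    if joined.isna().all(axis=None):
        raise UsageError("DE runs share no genes")
    fc = joined[[c for c in joined if c.startswith("fc")]]
    if variant == "mean_abs_fc":
        pi = fc.abs().mean(axis=1)
    elif variant == "de_count":
        q = joined[[c for c in joined if c.startswith("q")]]
        pi = ((q.to_numpy() < 0.05) & (fc.abs().to_numpy() > 1.0)).sum(axis=1).astype(float)
        pi = pd.Series(pi, index=joined.index)
    else:
        raise UsageError(f"unknown pi variant {variant!r}")
    pi[fc.isna().any(axis=1)] = np.nan
    return pi.rename("pi")


def quantile_select(
    values: pd.Series, low: float = 0.10, high: float = 0.90
) -> tuple[set, set]:
    """Genes in the lower and upper tails of a value distribution.

    Cutoffs are linear-interpolation (type 7) quantiles; ties at a cutoff are
    kept inclusively.  Requires >= 10 non-missing values.
    """
    v = values.dropna()
    if len(v) < 10:
        raise UsageError(f"need >= 10 non-missing values, got {len(v)}")
    lo_cut = float(np.quantile(v, low))
    hi_cut = float(np.quantile(v, high))
    if lo_cut == hi_cut:
        warnings.warn("degenerate value distribution: tails coincide", stacklevel=2)
    return set(v.index[v <= lo_cut]), set(v.index[v >= hi_cut])
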
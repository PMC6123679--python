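"""Normalization, sex-differential expression testing, and gene-class calls.

The workflow mirrors the standard count-based RNA-seq recipe: filter weakly
expressed genes on counts-per-million, compute trimmed-mean-of-M-values (TMM)
normalization factors, test each gene with an exact conditional binomial test
on group-summed counts against effective library sizes, adjust p-values with
Benjamini-Hochberg, and call sex-biased genes at |log2FC| > 1, FDR < 0.05
(strong bias at |log2FC| >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .errors import ComputationError, UsageError

FEMALE = "female_biased"
MALE = "male_biased"
UNBIASED = "unbiased"
FILTERED = "filtered"


@dataclass
class GeneSets:
    """The six gene classes used throughout the downstream analyses."""

    fem: set = field(default_factory=set)
    male: set = field(default_factory=set)
    fem_fc3: set = field(default_factory=set)
    male_fc3: set = field(default_factory=set)
    fem_6sp: set = field(default_factory=set)
    male_6sp: set = field(default_factory=set)
    ub: set = field(default_factory=set)

    @property
    def sb(self) -> set:
        return self.fem | self.male

    def named(self) -> dict[str, set]:
        return {
            "Fem": self.fem,
            "Male": self.male,
            "SB": self.sb,
            "Fem_FC3": self.fem_fc3,
            "Male_FC3": self.male_fc3,
            "Fem_6SP": self.fem_6sp,
            "Male_6SP": self.male_6sp,
            "UB": self.ub,
        }

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set().union(*self.named().values()))
        data = {name: [g in s for g in genes] for name, s in self.named().items()}
        return pd.DataFrame(data, index=pd.Index(genes, name="gene")).astype(int)


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw, or TMM-effective, library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    return counts / lib * 1e6


def compute_tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric-mean-scaled to 1.

    M-values (log-ratio vs the reference sample) are trimmed by ``trim_m`` on
    each side and A-values (log-abundance) by ``trim_a``; the factor is the
    inverse-variance-weighted mean of the surviving M-values, using the
    binomial asymptotic variance.  Genes with a zero count in either member
    of a pair are excluded from that pair's trim set.  The reference defaults
    to the sample whose upper-quartile cpm is closest to the mean.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = cm.sample_ids[lib == 0][0]
        raise ComputationError(f"sample {bad!r} has zero total counts")
    if counts.shape[1] < 2:
        raise UsageError("TMM needs at least two samples")
    cpm_mat = counts / lib * 1e6
    if reference is None:
        f75 = np.quantile(cpm_mat, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference not in cm.sample_ids:
            raise UsageError(f"unknown reference sample {reference!r}")
        ref_idx = list(cm.sample_ids).index(reference)
    yr, nr = counts[:, ref_idx], lib[ref_idx]
    log_factors = np.zeros(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref_idx:
            continue
        ys, ns = counts[:, s], lib[s]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            continue
        m = np.log2((ys[keep] / ns) / (yr[keep] / nr))
        a = 0.5 * np.log2((ys[keep] / ns) * (yr[keep] / nr))
        v = (ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        n = len(m)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            continue
        f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
        log_factors[s] = 0.0 if abs(f) < 1e-6 else f
    factors = np.exp2(log_factors)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def cpm_filter(
    cm: CountMatrix, threshold: float = 0.5
) -> tuple[CountMatrix, list[str]]:
    """Drop genes with cpm below ``threshold`` in more than half of the samples.

    A gene is retained iff its cpm reaches the threshold in at least
    ceil(n_samples / 2) samples, so the "exactly half below" boundary case is
    retained.  cpm is computed on raw library sizes.
    """
    c = cpm(cm.counts)
    n = cm.shape[1]
    ok = (c >= threshold).sum(axis=1) >= int(np.ceil(n / 2))
    filtered = list(cm.gene_ids[~ok])
    return CountMatrix(cm.counts.loc[ok], cm.samples), filtered


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, ties preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exact_de_test(
    cm: CountMatrix,
    group_key: str = "sex",
    factors: pd.Series | None = None,
    numerator: str | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene exact conditional test of two groups on summed counts.

    Under the null the group-1 total of each gene is binomial given the gene
    total, with success probability the group-1 share of the summed effective
    library sizes (library size x TMM factor).  The two-sided p doubles the
    smaller tail (capped at 1).  log2FC is computed from group means of
    counts rescaled to a common effective library size, with a prior count.

    For a ``sex`` grouping the numerator defaults to female, so positive
    log2FC means female-biased.
    """
    groups = {k: v for k, v in cm.groups(group_key).items() if v}
    if len(groups) != 2:
        raise UsageError(f"need exactly 2 groups for {group_key!r}, got {sorted(groups)}")
    if numerator is None:
        numerator = "female" if "female" in groups else sorted(groups)[0]
    if numerator not in groups:
        raise UsageError(f"numerator group {numerator!r} not present")
    denominator = next(g for g in groups if g != numerator)
    for g, ids in groups.items():
        if len(ids) < 2:
            raise UsageError(f"group {g!r} has fewer than 2 samples")
    if factors is None:
        factors = compute_tmm_factors(cm)
    lib = cm.library_sizes().astype(float)
    eff = lib * factors
    g1, g2 = groups[numerator], groups[denominator]
    y1 = cm.counts[g1].sum(axis=1).to_numpy()
    y2 = cm.counts[g2].sum(axis=1).to_numpy()
    t = y1 + y2
    pi = eff[g1].sum() / (eff[g1].sum() + eff[g2].sum())
    lower = stats.binom.cdf(y1, t, pi)
    upper = stats.binom.sf(y1 - 1, t, pi)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[t == 0] = 1.0
    mean_eff = float(np.exp(np.mean(np.log(eff))))
    z = cm.counts.to_numpy(dtype=float) / eff.to_numpy() * mean_eff
    zdf = pd.DataFrame(z, index=cm.gene_ids, columns=cm.sample_ids)
    m1 = zdf[g1].mean(axis=1).to_numpy()
    m2 = zdf[g2].mean(axis=1).to_numpy()
    log2fc = np.log2((m1 + prior_count) / (m2 + prior_count))
    return pd.DataFrame(
        {"gene": cm.gene_ids, "log2fc": log2fc, "p": p, "fdr": bh_fdr(p)}
    ).reset_index(drop=True)


def de_pipeline(
    cm: CountMatrix, group_key: str = "sex", numerator: str | None = None
) -> pd.DataFrame:
    """Filter, normalize, test and adjust; filtered genes carry label 'filtered'."""
    kept, filtered = cpm_filter(cm)
    factors = compute_tmm_factors(kept)
    res = exact_de_test(kept, group_key, factors=factors, numerator=numerator)
    res["label"] = UNBIASED
    if filtered:
        pad = pd.DataFrame(
            {
                "gene": filtered,
                "log2fc": np.nan,
                "p": np.nan,
                "fdr": np.nan,
                "label": FILTERED,
            }
        )
        res = pd.concat([res, pad], ignore_index=True)
    return res


def call_sb_genes(
    results: pd.DataFrame,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    strong_fc: float = 3.0,
) -> tuple[GeneSets, pd.DataFrame]:
    """Build the gene classes from DE results.

    Female-biased: log2FC > fc_threshold (strict) and FDR < fdr_threshold;
    male-biased symmetric with the negated threshold; strong-bias subsets use
    |log2FC| >= strong_fc (inclusive).  UB is every tested, unfiltered gene
    not called sex-biased.  Returns the sets and the labeled result table.
    """
    res = results.copy()
    tested = res["p"].notna() if "p" in res else pd.Series(True, index=res.index)
    sig = tested & (res["fdr"] < fdr_threshold)
    fem_mask = sig & (res["log2fc"] > fc_threshold)
    male_mask = sig & (res["log2fc"] < -fc_threshold)
    sets = GeneSets(
        fem=set(res.loc[fem_mask, "gene"]),
        male=set(res.loc[male_mask, "gene"]),
        fem_fc3=set(res.loc[fem_mask & (res["log2fc"] >= strong_fc), "gene"]),
        male_fc3=set(res.loc[male_mask & (res["log2fc"] <= -strong_fc), "gene"]),
        ub=set(res.loc[tested & ~fem_mask & ~male_mask, "gene"]),
    )
    labels = np.where(
        fem_mask, FEMALE, np.where(male_mask, MALE, np.where(tested, UNBIASED, FILTERED))
    )
    res["label"] = labels
    return sets, res


def conserved_sb(per_species_sets: list[GeneSets]) -> tuple[set, set]:
    """Genes with the same sex bias in every species (per direction)."""
    if not per_species_sets:
        raise UsageError("no species sets provided")
    fem = set.intersection(*(s.fem for s in per_species_sets))
    male = set.intersection(*(s.male for s in per_species_sets))
    return fem, male
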
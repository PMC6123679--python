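"""Tests of genomic clustering of labeled genes along chromosomes.

The primary statistic is a Markov-chain odds score: a first-order chain of
the ordered binary membership labels is fitted by maximum likelihood and its
likelihood compared with an independence (Bernoulli) null, on the log10
scale.  The score is non-negative by nesting and high when same-label genes
run together.  Significance comes from within-chromosome label permutation.
Two Fisher's exact variants complement it: association between consecutive
labels (adjacency, a contiguity test) and per-chromosome enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneMap
from .errors import UsageError


def _transition_counts(mat: np.ndarray) -> tuple[np.ndarray, ...]:
    """n00, n01, n10, n11 per row of a 2-D 0/1 label array."""
    a = mat[:, :-1]
    b = mat[:, 1:]
    n11 = (a * b).sum(axis=1)
    n10 = (a * (1 - b)).sum(axis=1)
    n01 = ((1 - a) * b).sum(axis=1)
    n00 = ((1 - a) * (1 - b)).sum(axis=1)
    return n00, n01, n10, n11


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # x * log(y) with the 0 * log(0) = 0 convention
    return np.where(x > 0, x * np.log(np.maximum(y, 1e-300)), 0.0)


def _batch_markov_scores(mat: np.ndarray) -> np.ndarray:
    """log10 likelihood-ratio scores for each row of a 0/1 label matrix."""
    mat = np.asarray(mat, dtype=np.int64)
    n = mat.shape[1]
    k = mat.sum(axis=1)
    n00, n01, n10, n11 = _transition_counts(mat)
    r0 = n00 + n01
    r1 = n10 + n11
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_markov = (
            _xlogy(n00, n00 / np.maximum(r0, 1))
            + _xlogy(n01, n01 / np.maximum(r0, 1))
            + _xlogy(n10, n10 / np.maximum(r1, 1))
            + _xlogy(n11, n11 / np.maximum(r1, 1))
        )
    p = k / n
    tail1 = mat[:, 1:].sum(axis=1)
    tail0 = (n - 1) - tail1
    ll_null = _xlogy(tail1, p) + _xlogy(tail0, 1.0 - p)
    score = (ll_markov - ll_null) / np.log(10.0)
    score[(k == 0) | (k == n)] = np.nan
    return np.maximum(score, 0.0)


def markov_odds(labels) -> float:
    """Markov-chain clustering odds score of one ordered 0/1 label sequence.

    Fits first-order transition probabilities by ML and compares, as a log10
    likelihood ratio, with independent Bernoulli(p = k/n) labels.  The score
    is >= 0; it is 0 exactly when empirical transition frequencies equal the
    marginal frequency.  Undefined (NaN) for all-0 or all-1 sequences.
    """
    arr = np.asarray(labels, dtype=np.int64)
    if arr.ndim != 1 or len(arr) < 2:
        raise UsageError("need a 1-D label sequence of length >= 2")
    if not np.isin(arr, (0, 1)).all():
        raise UsageError("labels must be 0/1")
    return float(_batch_markov_scores(arr[None, :])[0])


def permutation_pvalue(labels, n_perm: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """(observed score, permutation p) for the Markov odds score.

    Labels are permuted within the chromosome; p uses the add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    arr = np.asarray(labels, dtype=np.int64)
    obs = markov_odds(arr)
    if np.isnan(obs):
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(arr, (n_perm, 1)), axis=1)
    scores = _batch_markov_scores(perms)
    p = (1.0 + np.sum(scores >= obs - 1e-12)) / (n_perm + 1.0)
    return obs, float(p)


def fisher_adjacency(labels) -> float:
    """Two-sided Fisher p for association between consecutive labels.

    The 2x2 table cross-tabulates the label of gene i with that of gene i+1
    over all adjacent pairs; single-label sequences give p = 1.
    """
    arr = np.asarray(labels, dtype=np.int64)
    if len(arr) < 3:
        raise UsageError("adjacency test needs >= 3 genes")
    n00, n01, n10, n11 = (int(v[0]) for v in _transition_counts(arr[None, :]))
    table = [[n11, n10], [n01, n00]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_enrichment(gene_map: GeneMap, target: set) -> pd.Series:
    """Per-chromosome two-sided Fisher p for over/under-representation.

    Tables are (target, non-target) x (on chromosome, elsewhere).
    """
    if len(gene_map) == 0:
        raise UsageError("empty gene map")
    t = gene_map.table
    in_target = t["gene"].isin(target)
    total_t = int(in_target.sum())
    total = len(t)
    out = {}
    for chrom in gene_map.chromosomes:
        on = t["chrom"] == chrom
        a = int((on & in_target).sum())
        b = total_t - a
        c = int(on.sum()) - a
        d = (total - total_t) - c
        out[chrom] = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return pd.Series(out, name="fisher_enrichment_p")


@dataclass
class ClusterTestResult:
    chrom: str
    n: int
    k: int
    odds_score: float
    permutation_p: float
    fisher_adjacency_p: float
    fisher_enrichment_p: float


def cluster_tests(
    gene_map: GeneMap, target: set, n_perm: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """All clustering tests for one gene set, per chromosome."""
    enrich = fisher_enrichment(gene_map, target)
    rows = []
    for i, chrom in enumerate(gene_map.chromosomes):
        seq = gene_map.label_sequence(chrom, target)
        n, k = len(seq), int(seq.sum())
        if 0 < k < n and n >= 3:
            score, p = permutation_pvalue(seq, n_perm=n_perm, seed=seed + i)
            adj = fisher_adjacency(seq)
        else:
            score, p, adj = float("nan"), float("nan"), 1.0
        rows.append(
            ClusterTestResult(chrom, n, k, score, p, adj, float(enrich[chrom])).__dict__
        )
    return pd.DataFrame(rows)
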
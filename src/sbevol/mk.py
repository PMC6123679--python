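"""McDonald-Kreitman-derived selection statistics.

Per-gene tables of non-synonymous / synonymous polymorphism (Pn, Ps) and
divergence (Dn, Ds) feed two statistics: the per-gene Direction of Selection
DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps), and the group-level unbiased neutrality index

    NI_TG = sum_i Ds_i Pn_i / (Ps_i + Ds_i) / sum_i Dn_i Ps_i / (Ps_i + Ds_i).

NI_TG > 1 indicates an excess of non-synonymous polymorphism (segregating
slightly deleterious variants); DoS > 0 suggests adaptive divergence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codon import BASES, CODON_TO_AA, STOP_CODONS, is_valid_codon
from .errors import UsageError

log = logging.getLogger(__name__)


def tabulate_polymorphism(variants: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pn / Ps counts from an annotated variant table.

    Expected columns: gene, ref_codon, codon_pos (0-based position within the
    codon), alt (alternative base).  Variants creating or destroying a stop
    codon are dropped; rows with alleles outside {A,C,G,T} or malformed
    codons are skipped with a warning.
    """
    required = {"gene", "ref_codon", "codon_pos", "alt"}
    if not required.issubset(variants.columns):
        raise UsageError(f"variant table missing columns {sorted(required - set(variants.columns))}")
    counts: dict[str, list[int]] = {}
    for row in variants.itertuples(index=False):
        ref = str(row.ref_codon).upper()
        alt = str(row.alt).upper()
        pos = int(row.codon_pos)
        if alt not in BASES or not is_valid_codon(ref) or not 0 <= pos <= 2:
            log.warning("skipping malformed variant row for gene %s", row.gene)
            continue
        mutant = ref[:pos] + alt + ref[pos + 1 :]
        if ref in STOP_CODONS or mutant in STOP_CODONS:
            continue  # stop-codon gain/loss removed
        syn = CODON_TO_AA[ref] == CODON_TO_AA[mutant]
        pn, ps = counts.setdefault(str(row.gene), [0, 0])
        counts[str(row.gene)] = [pn + (not syn), ps + syn]
    genes = sorted(counts)
    return pd.DataFrame(
        {
            "gene": genes,
            "Pn": [counts[g][0] for g in genes],
            "Ps": [counts[g][1] for g in genes],
        }
    )


def dos(counts: pd.DataFrame) -> pd.Series:
    """Per-gene Direction of Selection; NaN when either denominator is zero."""
    d_tot = counts["Dn"] + counts["Ds"]
    p_tot = counts["Pn"] + counts["Ps"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts["Dn"] / d_tot - counts["Pn"] / p_tot
    out[(d_tot == 0) | (p_tot == 0)] = np.nan
    return out.rename("dos")


def ni_tg(counts: pd.DataFrame) -> float:
    """Group-level unbiased neutrality index over a set of genes.

    Genes with Ps + Ds = 0 are skipped; NaN (with a warning) when the
    denominator sum is zero.
    """
    if len(counts) == 0:
        return float("nan")
    w = counts["Ps"] + counts["Ds"]
    usable = counts[w > 0]
    if len(usable) == 0:
        return float("nan")
    denom_w = usable["Ps"] + usable["Ds"]
    num = (usable["Ds"] * usable["Pn"] / denom_w).sum()
    den = (usable["Dn"] * usable["Ps"] / denom_w).sum()
    if den == 0:
        log.warning("NI_TG denominator sum is zero")
        return float("nan")
    return float(num / den)


def ni_tg_bootstrap(
    counts: pd.DataFrame, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, float, float]:
    """NI_TG with a nonparametric bootstrap CI (resampling genes)."""
    rng = np.random.default_rng(seed)
    point = ni_tg(counts)
    reps = []
    n = len(counts)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps.append(ni_tg(counts.iloc[idx]))
    reps = np.asarray(reps, dtype=float)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanquantile(reps, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def merge_divergence(
    polymorphism: pd.DataFrame, rates: pd.DataFrame
) -> pd.DataFrame:
    """Attach Dn / Ds from a rates table (columns nd, sd) to Pn / Ps counts.

    Pathway-averaged substitution counts are rounded half-to-even to
    integers, matching the integer-count contract of the MK table.
    """
    div = rates[["gene", "nd", "sd"]].copy()
    div["Dn"] = np.rint(div.pop("nd")).astype(int)
    div["Ds"] = np.rint(div.pop("sd")).astype(int)
    return polymorphism.merge(div, on="gene", how="inner")
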
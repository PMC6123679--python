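"""Lineage-specific dN/dS on trio codon alignments.

The estimator is a counting scheme: codon columns are cleaned of gaps and
ambiguity, poorly aligned windows are masked with a SWAMP-style sliding
window, substitutions are assigned to the focal branch by outgroup parsimony,
multi-step codon changes are averaged over minimal mutational pathways, site
counts follow transition-weighted Nei-Gojobori opportunity counting, and
rates receive a Jukes-Cantor multiple-hit correction.  Gene-level filters
reproduce the usual saturation and low-information gates (dS > 2,
N*dN < 1 or S*dS < 1, alignments shorter than 100 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import (
    CODON_TO_AA,
    STOP_CODONS,
    codon_sites,
    is_valid_codon,
    pathway_counts,
    split_codons,
)
from .containers import TrioAlignment
from .errors import ComputationError

MIN_ALIGNMENT_BP = 100
SHORT_ALIGNMENT = "short_alignment"
MASKED_SHORT = "masked_short"
SATURATED = "saturated_dS"
LOW_COUNT = "low_count"


@dataclass
class RateRecord:
    """Per-gene site counts, focal-branch substitution counts and rates."""

    gene_id: str
    n_sites: float = np.nan  # non-synonymous sites N
    s_sites: float = np.nan  # synonymous sites S
    nd: float = np.nan
    sd: float = np.nan
    dn: float = np.nan
    ds: float = np.nan
    omega: float = np.nan
    ambiguous: int = 0
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "N": self.n_sites,
            "S": self.s_sites,
            "nd": self.nd,
            "sd": self.sd,
            "dN": self.dn,
            "dS": self.ds,
            "omega": self.omega,
            "ambiguous": self.ambiguous,
            "flags": ";".join(sorted(self.flags)),
        }


def clean_alignment(trio: TrioAlignment) -> TrioAlignment:
    """Remove every codon column containing a gap or N in any sequence.

    Removal is by whole codon so the reading frame is preserved; alignments
    left shorter than 100 bp are flagged.
    """
    cols = zip(
        split_codons(trio.focal), split_codons(trio.sister), split_codons(trio.outgroup)
    )
    keep = [(f, s, o) for f, s, o in cols if all(is_valid_codon(c) for c in (f, s, o))]
    focal = "".join(f for f, _, _ in keep)
    sister = "".join(s for _, s, _ in keep)
    outgroup = "".join(o for _, _, o in keep)
    flags = set(trio.flags)
    if len(focal) < MIN_ALIGNMENT_BP:
        flags.add(SHORT_ALIGNMENT)
    return trio.replace(focal=focal, sister=sister, outgroup=outgroup, flags=flags)


def _nonsyn_difference(c1: str, c2: str) -> bool:
    if not (is_valid_codon(c1) and is_valid_codon(c2)) or c1 == c2:
        return False
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        return False
    return CODON_TO_AA[c1] != CODON_TO_AA[c2]


def mask_alignment(
    trio: TrioAlignment, cutoff: int = 4, window: int = 5, min_len_bp: int = 75
) -> TrioAlignment:
    """SWAMP-style masking of poorly aligned regions.

    Each non-focal sequence is scanned against the focal one in windows of
    ``window`` codons; when at least ``cutoff`` codons in a window differ
    non-synonymously, all window codons are masked (set to N) in that
    sequence.  Windows are evaluated on the unmasked input, then masks are
    applied.  Sequences whose unmasked span falls below ``min_len_bp`` are
    flagged for exclusion.
    """
    focal = split_codons(trio.focal)
    n = len(focal)
    flags = set(trio.flags)
    if window > n:
        return trio.replace(flags=flags)
    masked_seqs = {}
    for name in ("sister", "outgroup"):
        codons = split_codons(getattr(trio, name))
        diff = [_nonsyn_difference(codons[i], focal[i]) for i in range(n)]
        to_mask: set[int] = set()
        for i in range(n - window + 1):
            if sum(diff[i : i + window]) >= cutoff:
                to_mask.update(range(i, i + window))
        for i in to_mask:
            codons[i] = "NNN"
        masked_seqs[name] = "".join(codons)
    out = trio.replace(sister=masked_seqs["sister"], outgroup=masked_seqs["outgroup"])
    for _, seq in out.items():
        span = sum(3 for c in split_codons(seq) if is_valid_codon(c))
        if span < min_len_bp:
            flags.add(MASKED_SHORT)
            break
    return out.replace(flags=flags)


def count_sites(seq: str, kappa: float = 1.0) -> tuple[float, float]:
    """(N, S) mutational-opportunity site counts for a gap-free codon sequence.

    ``kappa`` = 1 gives the classic equal-rate Nei-Gojobori count; larger
    values weight transitions, matching a transition-biased mutation process.
    In-frame stop codons raise an error naming the codon index.
    """
    s = n = 0.0
    for i, codon in enumerate(split_codons(seq)):
        if codon in STOP_CODONS:
            raise ComputationError(f"in-frame stop codon at codon index {i}")
        cs, cn = codon_sites(codon, kappa)
        s += cs
        n += cn
    return n, s


def _usable_columns(trio: TrioAlignment) -> list[tuple[str, str, str]]:
    cols = zip(
        split_codons(trio.focal), split_codons(trio.sister), split_codons(trio.outgroup)
    )
    return [
        (f, s, o)
        for f, s, o in cols
        if all(is_valid_codon(c) and c not in STOP_CODONS for c in (f, s, o))
    ]


def lineage_substitutions(trio: TrioAlignment) -> tuple[float, float, int]:
    """Focal-branch (nd, sd) substitution counts by outgroup parsimony.

    Per variable codon column: focal != sister with sister == outgroup is a
    focal-branch change; focal == sister != outgroup is an outgroup-side
    change (ignored); any other disagreement pattern is ambiguous, skipped
    and counted.  Multi-step codon changes are averaged over minimal
    stop-free pathways.
    """
    nd = sd = 0.0
    ambiguous = 0
    for f, s, o in _usable_columns(trio):
        if f == s:
            continue
        if s == o:
            counts = pathway_counts(s, f)
            if counts is None:
                ambiguous += 1
                continue
            csd, cnd = counts
            sd += csd
            nd += cnd
        else:
            ambiguous += 1
    return nd, sd, ambiguous


def _jukes_cantor(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return np.nan
    return -0.75 * math.log(arg)


def estimate_rates(trio: TrioAlignment, kappa: float = 2.0) -> RateRecord:
    """Clean/masked trio -> RateRecord with JC-corrected focal dN, dS, omega.

    Site counts are taken on the focal sequence over the columns usable for
    substitution counting.  dX = -(3/4) ln(1 - 4 pX / 3); the saturation flag
    is set when the correction argument is non-positive; omega is missing
    when dS is 0 or undefined.
    """
    rec = RateRecord(trio.gene_id, flags=set(trio.flags))
    cols = _usable_columns(trio)
    if not cols:
        rec.flags.add(SHORT_ALIGNMENT)
        return rec
    focal_seq = "".join(f for f, _, _ in cols)
    rec.n_sites, rec.s_sites = count_sites(focal_seq, kappa)
    rec.nd, rec.sd, rec.ambiguous = lineage_substitutions(trio)
    if rec.n_sites <= 0 or rec.s_sites <= 0:
        rec.flags.add(LOW_COUNT)
        return rec
    rec.dn = _jukes_cantor(rec.nd / rec.n_sites)
    rec.ds = _jukes_cantor(rec.sd / rec.s_sites)
    if np.isnan(rec.dn) or np.isnan(rec.ds):
        rec.flags.add(SATURATED)
    if not np.isnan(rec.dn) and not np.isnan(rec.ds) and rec.ds > 0:
        rec.omega = rec.dn / rec.ds
    return rec


def process_trio(trio: TrioAlignment, kappa: float = 2.0, mask: bool = True) -> RateRecord:
    """Full per-gene path: clean, (optionally) mask, estimate."""
    cleaned = clean_alignment(trio)
    if mask and SHORT_ALIGNMENT not in cleaned.flags:
        cleaned = mask_alignment(cleaned)
    return estimate_rates(cleaned, kappa)


def filter_rates(
    records: list[RateRecord], max_ds: float = 2.0, min_info: float = 1.0
) -> tuple[list[RateRecord], list[RateRecord]]:
    """Apply the saturation and low-information gates.

    Excluded: dS > 2 (or undefined/saturated), N*dN < 1, S*dS < 1, or an
    alignment flagged short before/after masking.
    """
    retained, excluded = [], []
    for rec in records:
        bad = (
            SHORT_ALIGNMENT in rec.flags
            or MASKED_SHORT in rec.flags
            or SATURATED in rec.flags
            or np.isnan(rec.dn)
            or np.isnan(rec.ds)
            or rec.ds > max_ds
            or rec.n_sites * rec.dn < min_info
            or rec.s_sites * rec.ds < min_info
        )
        (excluded if bad else retained).append(rec)
    return retained, excluded


def rates_table(records: list[RateRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
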
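"""Core in-memory containers for the pipeline.

``CountMatrix`` wraps a genes x samples integer count table plus per-sample
metadata, ``GeneMap`` the genomic placement of genes (ordinal ranks along
chromosomes), and ``TrioAlignment`` a codon-aligned focal/sister/outgroup
sequence triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

METADATA_COLUMNS = ("tissue", "sex", "condition", "stage", "species")


@dataclass
class CountMatrix:
    """Gene-level read counts (genes x samples) with sample metadata.

    ``counts`` is indexed by gene id with sample ids as columns; ``samples``
    is indexed by sample id and carries tissue, sex, condition, stage and
    species columns (missing values allowed, encoded as "NA").
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(vals < 0):
            raise FormatError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.samples = self.samples.loc[self.counts.columns]
        for col in METADATA_COLUMNS:
            if col not in self.samples.columns:
                self.samples[col] = "NA"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.samples)

    def groups(self, key: str) -> dict[str, list[str]]:
        """Sample ids grouped by a metadata column."""
        out: dict[str, list[str]] = {}
        for sid, val in self.samples[key].items():
            out.setdefault(str(val), []).append(sid)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.samples[
            list(METADATA_COLUMNS)
        ].astype(str).equals(other.samples[list(METADATA_COLUMNS)].astype(str))


@dataclass
class GeneMap:
    """Per-gene chromosome, start coordinate (0-based) and ordinal rank.

    ``table`` columns: gene, chrom, start, rank, family (optional, may be
    NA).  Ranks are contiguous from 0 within each chromosome, ordered by
    start with ties broken by gene id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"gene", "chrom", "start", "rank"}
        if not required.issubset(t.columns):
            raise FormatError(f"gene map missing columns {sorted(required - set(t.columns))}")
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r} in gene map")
        if "family" not in t.columns:
            t["family"] = pd.NA
        for chrom, sub in t.groupby("chrom", sort=False):
            ranks = np.sort(sub["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(len(sub))):
                raise FormatError(f"ranks on {chrom} are not contiguous from 0")
            ordered = sub.sort_values("rank")
            if not ordered["start"].is_monotonic_increasing:
                raise FormatError(f"start coordinates on {chrom} not non-decreasing in rank")
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def label_sequence(self, chrom: str, target: set[str]) -> np.ndarray:
        """Binary membership labels along one chromosome, ordered by rank."""
        sub = self.table[self.table["chrom"] == chrom].sort_values("rank")
        return sub["gene"].isin(target).to_numpy().astype(np.int8)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TrioAlignment:
    """Codon-aligned CDS for the focal species, its sister, and an outgroup."""

    gene_id: str
    focal: str
    sister: str
    outgroup: str
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lens = {len(self.focal), len(self.sister), len(self.outgroup)}
        if len(lens) != 1:
            raise FormatError(f"{self.gene_id}: aligned sequences differ in length")
        (length,) = lens
        if length % 3 != 0:
            raise FormatError(f"{self.gene_id}: alignment length {length} not a multiple of 3")
        allowed = set("ACGTN-")
        for name, seq in self.items():
            bad = set(seq.upper()) - allowed
            if bad:
                raise FormatError(f"{self.gene_id}/{name}: invalid characters {sorted(bad)}")
        self.focal = self.focal.upper()
        self.sister = self.sister.upper()
        self.outgroup = self.outgroup.upper()

    def items(self) -> list[tuple[str, str]]:
        return [("focal", self.focal), ("sister", self.sister), ("outgroup", self.outgroup)]

    @property
    def n_codons(self) -> int:
        return len(self.focal) // 3

    def replace(self, focal=None, sister=None, outgroup=None, flags=None) -> "TrioAlignment":
        return TrioAlignment(
            self.gene_id,
            focal if focal is not None else self.focal,
            sister if sister is not None else self.sister,
            outgroup if outgroup is not None else self.outgroup,
            set(self.flags) if flags is None else set(flags),
        )
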
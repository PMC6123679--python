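"""Readers and writers for the on-disk formats.

Counts and metadata travel as TSV, gene maps as BED (0-based half-open),
trio alignments as 3-record FASTA with role suffixes _F/_S/_O, MK counts
and gene sets as TSV, and run configuration as YAML.  Reader/writer pairs
are lossless round trips on valid data; format errors name the file and,
where meaningful, the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, GeneMap, TrioAlignment
from .errors import ConfigError, FormatError
from .simulate import SimConfig

log = logging.getLogger(__name__)

ROLE_SUFFIX = {"_F": "focal", "_S": "sister", "_O": "outgroup"}


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.samples.rename_axis("sample").to_csv(metadata_path, sep="\t")


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if not all(pd.api.types.is_numeric_dtype(d) for d in counts.dtypes):
        raise FormatError(f"{counts_path}: non-numeric count entry")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str).fillna("NA")
    try:
        return CountMatrix(counts, meta)
    except FormatError as exc:
        raise FormatError(f"{counts_path}: {exc}") from exc


def write_gene_map(gene_map: GeneMap, path) -> None:
    t = gene_map.table
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["start"],
            "end": t["start"] + 1_000,  # nominal 1 kb gene span
            "gene": t["gene"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_map(path) -> GeneMap:
    """BED-like TSV (chrom, start, end, gene) -> GeneMap with derived ranks.

    Ranks come from sorting on (chromosome, start), ties broken by gene id.
    """
    try:
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene"],
            dtype={"chrom": str, "gene": str},
        )
    except pd.errors.EmptyDataError:
        log.warning("%s: empty gene map", path)
        return GeneMap(pd.DataFrame(columns=["gene", "chrom", "start", "rank"]))
    if bed["gene"].duplicated().any():
        dup = bed.loc[bed["gene"].duplicated(), "gene"].iloc[0]
        line = int(bed.index[bed["gene"] == dup][1]) + 1
        raise FormatError(f"{path}:{line}: duplicate gene id {dup!r}")
    bed = bed.sort_values(["chrom", "start", "gene"], kind="mergesort").reset_index(drop=True)
    bed["rank"] = bed.groupby("chrom", sort=False).cumcount()
    return GeneMap(bed[["gene", "chrom", "start", "rank"]])


def write_trio_fasta(trio: TrioAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{trio.gene_id}{suffix}", description="")
        for suffix, seq in zip(("_F", "_S", "_O"), (trio.focal, trio.sister, trio.outgroup))
    ]
    SeqIO.write(records, str(path), "fasta")


def read_trio_fasta(path) -> TrioAlignment:
    """3-record codon-aligned FASTA with role suffixes _F/_S/_O."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise FormatError(f"{path}: expected 3 records, found {len(records)}")
    roles: dict[str, str] = {}
    gene_id = None
    for rec in records:
        suffix = rec.id[-2:]
        if suffix not in ROLE_SUFFIX:
            raise FormatError(f"{path}: record {rec.id!r} lacks a _F/_S/_O role suffix")
        roles[ROLE_SUFFIX[suffix]] = str(rec.seq)
        gene_id = rec.id[:-2]
    if set(roles) != {"focal", "sister", "outgroup"}:
        raise FormatError(f"{path}: missing role among focal/sister/outgroup")
    try:
        return TrioAlignment(gene_id, roles["focal"], roles["sister"], roles["outgroup"])
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_trio_dir(alignments: list[TrioAlignment], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trio in alignments:
        write_trio_fasta(trio, outdir / f"{trio.gene_id}.fasta")


def read_trio_dir(directory) -> list[TrioAlignment]:
    return [read_trio_fasta(p) for p in sorted(Path(directory).glob("*.fasta"))]


def write_mk_counts(counts: pd.DataFrame, path) -> None:
    counts[["gene", "Pn", "Ps", "Dn", "Ds"]].to_csv(path, sep="\t", index=False)


def read_mk_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "Pn", "Ps", "Dn", "Ds"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    num = df[["Pn", "Ps", "Dn", "Ds"]]
    if (num < 0).any().any():
        raise FormatError(f"{path}: negative count entry")
    return df


def write_gene_sets(sets_frame: pd.DataFrame, path) -> None:
    sets_frame.to_csv(path, sep="\t")


def read_gene_sets(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {col: set(df.index[df[col] == 1]) for col in df.columns}


def load_config(path, overrides: dict | None = None) -> SimConfig:
    """YAML -> SimConfig; keyword overrides (e.g. CLI flags) win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    sim = raw.get("simulate", raw)
    sim = dict(sim)
    sim.update(overrides or {})
    if "branch_lengths" in sim:
        sim["branch_lengths"] = tuple(sim["branch_lengths"])
    try:
        return SimConfig(**sim)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
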
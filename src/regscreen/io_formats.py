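"""Readers and writers for the pipeline's file formats.

BED peak files (3-6+ columns, 0-based half-open), a minimal gene table
TSV, the gene x cell-type expression TSV, and the JSON run summary.
Readers never reorder records and never normalize chromosome names unless
asked; both are explicit downstream choices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "PeakFile",
    "GeneModel",
    "GeneTable",
    "ExpressionTable",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "write_expression_table",
    "write_summary",
    "BedParseError",
    "SchemaError",
]


class BedParseError(ValueError):
    """A malformed BED line; message carries the 1-based line number."""


class SchemaError(ValueError):
    """A tabular input missing required columns or violating a constraint."""


@dataclasses.dataclass(frozen=True)
class PeakFile:
    """A peak file on disk plus what it measures.

    ``label`` names the antibody target (a factor such as Olig2, or a
    histone mark such as H3K4me3); ``replicate`` is a 1-based replicate
    number when the experiment was replicated.
    """

    path: Path
    label: str
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("PeakFile label must be non-empty")
        if self.replicate is not None and self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def read(self, normalize_chrom_names: bool = False) -> IntervalSet:
        return read_bed(self.path, normalize_chrom_names=normalize_chrom_names)


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what the screen needs: TSS, strand, biotype."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")


@dataclasses.dataclass
class GeneTable:
    """Collection of :class:`GeneModel` with unique identifiers."""

    records: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.records:
            if g.gene_id in seen:
                raise SchemaError(f"duplicate gene_id {g.gene_id!r} in gene table")
            seen.add(g.gene_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.records]

    def get(self, gene_id: str) -> GeneModel:
        for g in self.records:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclasses.dataclass
class ExpressionTable:
    """Gene x cell-type expression values (counts or normalized units).

    ``matrix`` is a pandas DataFrame indexed by gene_id with one column
    per cell type, all entries non-negative.
    """

    matrix: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    def unmatched(self, genes: GeneTable) -> tuple[list[str], list[str]]:
        """Genes present in only one of (this table, the annotation).

        Returns (in_expression_only, in_annotation_only); nothing is ever
        silently dropped.
        """
        expr = set(self.matrix.index)
        anno = set(genes.ids())
        return sorted(expr - anno), sorted(anno - expr)


def _maybe_strip_chr(chrom: str, normalize: bool) -> str:
    if normalize and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def read_bed(path: str | Path, normalize_chrom_names: bool = False) -> IntervalSet:
    """Parse a BED file into an :class:`IntervalSet` in file order.

    Columns 1-6 are interpreted (chrom, start, end, name, score, strand);
    further columns ride along opaquely in ``extra``. Track, browser and
    ``#`` comment lines are skipped. An empty file yields an empty set.

    Raises
    ------
    BedParseError
        On non-integer coordinates, start >= end, or < 3 fields, naming
        the offending line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            try:
                iv = GenomicInterval(
                    chrom=_maybe_strip_chr(fields[0], normalize_chrom_names),
                    start=start,
                    end=end,
                    name=name,
                    score=score,
                    strand=strand,
                    extra=tuple(fields[6:]),
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return IntervalSet(out)


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(score)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, emitting only the populated columns.

    Round-trips the output of :func:`read_bed` byte-identically for
    well-formed input (integer scores are written without decimals).
    """
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            n_cols = 3
            if iv.extra:
                n_cols = 6 + len(iv.extra)
            elif iv.strand is not None:
                n_cols = 6
            elif iv.score is not None:
                n_cols = 5
            elif iv.name is not None:
                n_cols = 4
            if n_cols > 3:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols > 4:
                fields.append(_format_score(iv.score))
            if n_cols > 5:
                fields.append(iv.strand if iv.strand is not None else ".")
            fields.extend(iv.extra)
            fh.write("\t".join(fields) + "\n")


_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "biotype"]


def read_gene_table(path: str | Path, normalize_chrom_names: bool = False) -> GeneTable:
    """Read the minimal gene annotation TSV.

    Required header columns: gene_id, chrom, strand, tss (0-based position
    of the first transcribed base), biotype. Duplicate gene identifiers or
    a strand outside {+,-} raise an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: gene table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            tss = int(row.tss)
        except ValueError as exc:
            raise SchemaError(f"{path}: non-integer tss for gene {row.gene_id}") from exc
        records.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=_maybe_strip_chr(str(row.chrom), normalize_chrom_names),
                strand=str(row.strand),
                tss=tss,
                biotype=str(row.biotype),
            )
        )
    return GeneTable(records)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.biotype) for g in genes],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read the gene x cell-type expression TSV (first column gene_id).

    Entries must be numeric and non-negative; violations raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None or df.shape[1] == 0:
        raise SchemaError(f"{path}: expected gene_id column plus >=1 cell-type column")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad = df.index[numeric.isna()][0]
            raise BedParseError(
                f"{path}: non-numeric expression value for gene {bad!r}, column {col!r}"
            )
        df[col] = numeric
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values are not allowed")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene_id {dup!r} in expression table")
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_summary(summary: dict, path: str | Path) -> None:
    """Write the run summary as pretty-printed JSON."""
    with Path(path).open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
        fh.write("\n")
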
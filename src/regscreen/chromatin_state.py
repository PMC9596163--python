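"""Chromatin-state classification of promoters and enhancers.

Elements are classified from co-occurrence of four histone marks:

* H3K4me3 — promoter-associated activation mark
* H3K27ac — activity mark at promoters and enhancers
* H3K4me1 — enhancer/poising mark
* H3K27me3 — Polycomb repression mark

Promoters are fixed windows around each annotated TSS (1000 bp upstream
through 10 bp downstream, 1010 bp total); any mark-covered footprint
outside promoter windows is treated as enhancer territory. The rule table:

===============  ====================================  ==========
locus kind       marks present                         state
===============  ====================================  ==========
promoter         H3K4me3 AND H3K27ac                   active
promoter         H3K27me3, no active mark              repressed
promoter         H3K4me1, no active/repressive mark    poised
enhancer         H3K27ac                               active
enhancer         H3K27me3, no H3K27ac                  repressed
enhancer         H3K4me1 only                          poised
any              anything else                         unclassified
===============  ====================================  ==========

"Active marks" are {H3K4me3, H3K27ac} at promoters and {H3K27ac} at
enhancers. Bivalent promoters (H3K4me3 + H3K27me3, no H3K27ac/H3K4me1)
fall through to unclassified by default; ``bivalent_as`` can reassign
them.

This module also builds the replicate-consensus peak set used for the
transcription-factor peaks: a replicate-1 peak is retained if it is
reproduced in replicate 2 or falls in a regulatory element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import (
    GenomicInterval,
    IntervalSet,
    filter_overlapping,
    normalize,
    overlaps,
    subtract,
)
from .io_formats import GeneModel, GeneTable

__all__ = [
    "MARKS",
    "RegulatoryElement",
    "promoter_window",
    "classify_element",
    "annotate_landscape",
    "consensus_peaks",
    "regulatory_footprint",
]

#: The four canonical histone marks, in display order.
MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3")

_STATES = ("active", "repressed", "poised", "unclassified")

# BED9 itemRgb per state for the debug/track export.
_STATE_RGB = {
    "active": "0,160,0",
    "repressed": "200,0,0",
    "poised": "230,160,0",
    "unclassified": "128,128,128",
}


@dataclass
class RegulatoryElement:
    """A classified genomic element: a gene promoter or an enhancer run."""

    interval: GenomicInterval
    locus_kind: str  # "promoter" | "enhancer"
    state: str  # "active" | "repressed" | "poised" | "unclassified"
    marks: frozenset[str] = field(default_factory=frozenset)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.locus_kind not in {"promoter", "enhancer"}:
            raise ValueError(f"unknown locus_kind {self.locus_kind!r}")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.locus_kind == "promoter" and self.gene_id is None:
            raise ValueError("promoter elements must carry a gene_id")
        bad = set(self.marks) - set(MARKS)
        if bad:
            raise ValueError(f"unknown marks {sorted(bad)}")

    def to_bed9(self) -> str:
        iv = self.interval
        name = f"{self.state}:{self.locus_kind}"
        if self.gene_id:
            name += f":{self.gene_id}"
        rgb = _STATE_RGB[self.state]
        return "\t".join(
            [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                name,
                "0",
                ".",
                str(iv.start),
                str(iv.end),
                rgb,
            ]
        )


def promoter_window(
    gene: GeneModel, upstream_bp: int = 1000, downstream_bp: int = 10
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clamped at 0.

    Covers ``upstream_bp`` bases upstream of the TSS through
    ``downstream_bp`` bases downstream; the TSS base counts as the first
    downstream base. With the defaults the window is 1010 bp: a + strand
    gene with TSS t gives ``[t-1000, t+10)``, a - strand gene
    ``[t-9, t+1001)``.
    """
    if gene.strand == "+":
        start = gene.tss - upstream_bp
        end = gene.tss + downstream_bp
    else:
        start = gene.tss - (downstream_bp - 1)
        end = gene.tss + upstream_bp + 1
    start = max(0, start)
    if start >= end:  # degenerate only if both extents are 0
        end = start + 1
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id, strand=gene.strand)


def classify_element(
    marks: frozenset[str] | set[str], locus_kind: str, bivalent_as: str | None = None
) -> str:
    """Apply the state rule table to a mark subset at one locus kind.

    ``bivalent_as`` optionally reassigns bivalent promoters
    (H3K4me3 + H3K27me3 without H3K27ac or H3K4me1), which the default
    rules leave unclassified.
    """
    marks = frozenset(marks)
    bad = marks - set(MARKS)
    if bad:
        raise ValueError(f"unknown mark name(s): {sorted(bad)}")
    if locus_kind == "promoter":
        active_marks = {"H3K4me3", "H3K27ac"}
        if active_marks <= marks:
            return "active"
        if "H3K27me3" in marks and not (marks & active_marks):
            return "repressed"
        if (
            "H3K4me1" in marks
            and "H3K27me3" not in marks
            and not (marks & active_marks)
        ):
            return "poised"
        if (
            bivalent_as is not None
            and marks == frozenset({"H3K4me3", "H3K27me3"})
        ):
            return bivalent_as
        return "unclassified"
    if locus_kind == "enhancer":
        if "H3K27ac" in marks:
            return "active"
        if "H3K27me3" in marks:
            return "repressed"
        if "H3K4me1" in marks:
            return "poised"
        return "unclassified"
    raise ValueError(f"unknown locus_kind {locus_kind!r}")


def annotate_landscape(
    mark_peaks: dict[str, IntervalSet],
    genes: GeneTable,
    upstream_bp: int = 1000,
    downstream_bp: int = 10,
    min_overlap_bp: int = 1,
    bivalent_as: str | None = None,
) -> list[RegulatoryElement]:
    """Build the classified promoter + enhancer landscape.

    One promoter element per gene (marks = marks with a peak overlapping
    the window by >= ``min_overlap_bp``), then enhancer elements as the
    maximal merged runs of mark coverage outside all promoter windows,
    each classified from the marks covering it. Every covered base ends
    up in exactly one of the two footprints.
    """
    bad = set(mark_peaks) - set(MARKS)
    if bad:
        raise ValueError(f"unknown mark name(s): {sorted(bad)}")

    norm_marks = {m: normalize(s) for m, s in mark_peaks.items()}

    elements: list[RegulatoryElement] = []
    windows: list[GenomicInterval] = []
    for gene in genes:
        window = promoter_window(gene, upstream_bp, downstream_bp)
        windows.append(window)
        present = frozenset(
            m
            for m, peaks in norm_marks.items()
            if filter_overlapping(IntervalSet([window]), peaks, min_overlap_bp)
        )
        elements.append(
            RegulatoryElement(
                interval=window,
                locus_kind="promoter",
                state=classify_element(present, "promoter", bivalent_as),
                marks=present,
                gene_id=gene.gene_id,
            )
        )

    all_marks = IntervalSet([iv for s in norm_marks.values() for iv in s])
    enhancer_runs = subtract(all_marks, IntervalSet(windows))
    for run in enhancer_runs:
        present = frozenset(
            m
            for m, peaks in norm_marks.items()
            if filter_overlapping(IntervalSet([run]), peaks, min_overlap_bp)
        )
        elements.append(
            RegulatoryElement(
                interval=run,
                locus_kind="enhancer",
                state=classify_element(present, "enhancer"),
                marks=present,
            )
        )
    return elements


def regulatory_footprint(elements: list[RegulatoryElement]) -> IntervalSet:
    """Intervals of elements carrying at least one mark.

    This is the "regulatory elements" universe used when rescuing
    replicate-1 peaks in :func:`consensus_peaks`: a bare unmarked promoter
    window is annotation, not chromatin evidence, so it is excluded.
    """
    return IntervalSet([e.interval for e in elements if e.marks])


def consensus_peaks(
    rep1: IntervalSet,
    rep2: IntervalSet,
    regulatory: IntervalSet,
    min_overlap_bp: int = 1,
) -> IntervalSet:
    """Replicate-consensus peak set anchored on replicate-1 coordinates.

    Keeps the union of (a) rep1 peaks reproduced in rep2 and (b) rep1
    peaks overlapping a regulatory element, deduplicated, in rep1 order.
    The result is always a subset of rep1.
    """
    in_rep2 = filter_overlapping(rep1, rep2, min_overlap_bp)
    in_reg = filter_overlapping(rep1, regulatory, min_overlap_bp)
    keep = {(iv.chrom, iv.start, iv.end) for iv in in_rep2}
    keep |= {(iv.chrom, iv.start, iv.end) for iv in in_reg}
    seen: set[tuple] = set()
    out: list[GenomicInterval] = []
    for iv in rep1:
        key = (iv.chrom, iv.start, iv.end)
        if key in keep and key not in seen:
            seen.add(key)
            out.append(iv)
    return IntervalSet(out)
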
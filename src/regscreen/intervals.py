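"""Genomic interval algebra on 0-based half-open coordinates.

Every set operation in the screen — replicate consensus, multi-factor
intersection, element overlap — reduces to the handful of primitives here.
They are implemented as sorted sweeps over plain dataclasses and verified
in the test suite against a per-base boolean-array oracle, so the rest of
the pipeline can treat them as exact.

Conventions
-----------
* Coordinates are 0-based, half-open ``[start, end)`` — BED maps directly.
* Overlap means >= 1 shared base: ``a.start < b.end and b.start < a.end``
  on the same chromosome. Abutting intervals do not overlap.
* ``normalize`` merges touching intervals (``end_i == start_j``): the
  screen reasons about covered footprints, not peak identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "normalize",
    "overlaps",
    "multi_intersect",
    "filter_overlapping",
    "subtract",
    "distance",
    "covered_length",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval ``chrom:[start, end)`` with optional metadata.

    ``extra`` holds any BED columns beyond the sixth, untouched, so that
    narrowPeak/broadPeak files survive a read/write round trip.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        """Floor midpoint, ``(start + end) // 2``."""
        return (self.start + self.end) // 2


@dataclass
class IntervalSet:
    """An ordered collection of intervals, possibly overlapping.

    Construction preserves input order; call :func:`normalize` for the
    sorted, merged, non-overlapping representation.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @classmethod
    def from_iter(cls, it: Iterable[GenomicInterval]) -> "IntervalSet":
        return cls(list(it))

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap_bp: int = 1) -> bool:
    """True iff *a* and *b* share at least ``min_overlap_bp`` bases."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap_bp


def normalize(s: IntervalSet) -> IntervalSet:
    """Sort by (chrom, start, end) and merge overlapping or touching runs.

    Metadata (name/score/strand) is dropped on merge; the result is a pure
    footprint. Covered length is preserved or reduced, never increased.
    """
    merged: list[GenomicInterval] = []
    order = sorted(s.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    for iv in order:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
            continue
        merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged)


def covered_length(s: IntervalSet) -> int:
    """Total number of bases covered by the set (after merging)."""
    return sum(len(iv) for iv in normalize(s))


def _pairwise_intersect(a: list[GenomicInterval], b: list[GenomicInterval]) -> list[GenomicInterval]:
    """Footprint intersection of two normalized same-chrom interval lists."""
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(GenomicInterval(a[i].chrom, lo, hi))
        if a[i].end <= b[j].end:
            i += 1
        else:
            j += 1
    return out


def multi_intersect(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Bases covered by at least one interval from *every* input set.

    Returns the common footprint as maximal normalized runs per
    chromosome. Order-invariant in its arguments and idempotent under
    repetition of a set.

    Raises
    ------
    ValueError
        If ``sets`` is empty.
    """
    if not sets:
        raise ValueError("multi_intersect requires at least one interval set")
    norm = [normalize(s) for s in sets]
    chroms = set.intersection(*(set(n.by_chrom()) for n in norm))
    result: list[GenomicInterval] = []
    for chrom in sorted(chroms):
        acc = norm[0].by_chrom()[chrom]
        for n in norm[1:]:
            acc = _pairwise_intersect(acc, n.by_chrom()[chrom])
            if not acc:
                break
        result.extend(acc)
    return IntervalSet(result)


def filter_overlapping(
    anchor: IntervalSet, other: IntervalSet, min_overlap_bp: int = 1
) -> IntervalSet:
    """Anchor intervals (kept whole, original order and metadata) that
    overlap any interval of *other* by >= ``min_overlap_bp`` bases."""
    other_by_chrom = {c: ivs for c, ivs in normalize(other).by_chrom().items()}
    kept: list[GenomicInterval] = []
    for iv in anchor:
        cands = other_by_chrom.get(iv.chrom)
        if not cands:
            continue
        # cands are sorted and disjoint; binary search for first candidate
        # ending after iv.start, then scan.
        lo, hi = 0, len(cands)
        while lo < hi:
            mid = (lo + hi) // 2
            if cands[mid].end <= iv.start:
                lo = mid + 1
            else:
                hi = mid
        for cand in cands[lo:]:
            if cand.start >= iv.end:
                break
            if min(iv.end, cand.end) - max(iv.start, cand.start) >= min_overlap_bp:
                kept.append(iv)
                break
    return IntervalSet(kept)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Footprint of *a* not covered by *b*, as normalized runs."""
    a_norm = normalize(a)
    b_by_chrom = normalize(b).by_chrom()
    out: list[GenomicInterval] = []
    for iv in a_norm:
        cursor = iv.start
        for cut in b_by_chrom.get(iv.chrom, []):
            if cut.end <= cursor:
                continue
            if cut.start >= iv.end:
                break
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return IntervalSet(out)


def distance(point: int, interval: GenomicInterval) -> int:
    """Distance in bp from *point* to the nearest base of *interval*.

    Zero if the point lies within ``[start, end)``. The caller is
    responsible for chromosome agreement.
    """
    if interval.start <= point < interval.end:
        return 0
    return min(abs(point - interval.start), abs(point - (interval.end - 1)))
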
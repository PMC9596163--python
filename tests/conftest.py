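"""Shared fixtures and brute-force oracles for the test suite.

The per-base oracle represents interval sets as boolean occupancy arrays
over a small chromosome and re-derives every set operation by direct
array logic, independently of the sorted-sweep implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from regscreen.intervals import GenomicInterval, IntervalSet

CHROM_LEN = 10_000


def coverage(intervals, length: int = CHROM_LEN) -> np.ndarray:
    """Boolean occupancy array of a single-chromosome interval set."""
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        cov[iv.start : min(iv.end, length)] = True
    return cov


def runs_to_intervals(cov: np.ndarray, chrom: str = "chr1") -> list[GenomicInterval]:
    """Maximal True-runs of an occupancy array, as intervals."""
    out = []
    padded = np.concatenate([[False], cov, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for start, end in zip(edges[::2], edges[1::2]):
        out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def oracle_normalize(s: IntervalSet) -> list[GenomicInterval]:
    return runs_to_intervals(coverage(s))


def oracle_multi_intersect(sets: list[IntervalSet]) -> list[GenomicInterval]:
    cov = np.ones(CHROM_LEN, dtype=bool)
    for s in sets:
        cov &= coverage(s)
    return runs_to_intervals(cov)


def oracle_filter_overlapping(anchor: IntervalSet, other: IntervalSet,
                              min_overlap_bp: int = 1) -> list[GenomicInterval]:
    kept = []
    for a in anchor:
        for b in other:
            if a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_overlap_bp:
                kept.append(a)
                break
    return kept


def random_interval_set(rng: np.random.Generator, max_intervals: int = 50,
                        length: int = CHROM_LEN) -> IntervalSet:
    n = int(rng.integers(0, max_intervals + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(start + 500, length) + 1))
        out.append(GenomicInterval("chr1", start, end))
    return IntervalSet(out)


def ivs(*pairs, chrom: str = "chr1") -> IntervalSet:
    """Shorthand: ivs((0, 10), (20, 30)) -> IntervalSet on chr1."""
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in pairs])


def spans(s) -> list[tuple[int, int]]:
    """(start, end) pairs of an interval collection, for easy assertions."""
    return [(iv.start, iv.end) for iv in s]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_dataset():
    """One noise-free synthetic landscape, shared across tests."""
    from regscreen.synthetic import SyntheticConfig, generate

    return generate(SyntheticConfig(seed=1))
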
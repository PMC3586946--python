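"""Genomic interval primitives.

All coordinates are 0-based half-open (BED-style) throughout the package;
converters at I/O boundaries handle GFF3's 1-based closed convention.
Strand is ``"+"`` or ``"-"`` and interval arithmetic (5' ends, upstream
extension) is strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; gaps and N are preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded span on a chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    start : 0-based inclusive start.
    end : 0-based exclusive end; must satisfy ``0 <= start < end``.
    strand : ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' boundary: ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end

    def overlaps(self, other: "GenomicInterval", same_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Intersection keeping this interval's strand, or None if disjoint."""
        if self.chrom != other.chrom:
            return None
        start = max(self.start, other.start)
        end = min(self.end, other.end)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Merge overlapping or abutting same-chromosome intervals.

    Strand is taken from the first interval of each merged group; callers
    that mix strands (e.g. coding masks, which apply on either strand) get a
    well-defined, order-independent result because input is sorted first.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, prev.strand)
        else:
            merged.append(iv)
    return tuple(merged)


def subtract_intervals(
    region: GenomicInterval, holes: Iterable[GenomicInterval]
) -> tuple[GenomicInterval, ...]:
    """Parts of *region* not covered by *holes* (merged first), left to right."""
    pieces: list[GenomicInterval] = []
    cursor = region.start
    for hole in merge_intervals(h for h in holes if h.overlaps(region)):
        clipped_start = max(hole.start, region.start)
        clipped_end = min(hole.end, region.end)
        if clipped_start > cursor:
            pieces.append(GenomicInterval(region.chrom, cursor, clipped_start, region.strand))
        cursor = max(cursor, clipped_end)
    if cursor < region.end:
        pieces.append(GenomicInterval(region.chrom, cursor, region.end, region.strand))
    return tuple(pieces)
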
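"""Promoter alignments and conserved-element (phylogenetic footprint) extraction.

Putative cis-elements are runs of >= 6 consecutive alignment columns in
which five focal mammals (human, chimp, mouse, rat, dog by default) all
carry the identical ungapped nucleotide. Inputs are multi-species alignments
(MAF blocks) on a designated reference genome; only the five focal rows
matter for conservation, additional rows are ignored.

Conventions:

- reference-gap columns (insertions in a non-reference species) are dropped;
  an element must be genomically contiguous on the reference, so a dropped,
  masked or uncovered position breaks a run;
- a species absent from a block renders its columns non-conserved;
- matching is case-insensitive (soft-masked bases allowed);
- when blocks overlap on the reference, the first block in input order wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import PromoterRegion
from .intervals import GenomicInterval, complement

logger = logging.getLogger(__name__)

DEFAULT_FOCAL_SPECIES = ("human", "chimp", "mouse", "rat", "dog")
MIN_ELEMENT_LENGTH = 6

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentRow:
    """One species' row of an alignment block (MAF 's' line)."""

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapped multi-species alignment block with a designated reference row."""

    rows: tuple[AlignmentRow, ...]
    ref_species: str

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        ref = self.ref_row
        ungapped = sum(1 for c in ref.text if c != "-")
        if ungapped != ref.size:
            raise ValueError("reference row size does not match ungapped text length")

    @property
    def ref_row(self) -> AlignmentRow:
        for row in self.rows:
            if row.species == self.ref_species:
                return row
        raise ValueError(f"reference species {self.ref_species!r} missing from block")

    def row_for(self, species: str) -> Optional[AlignmentRow]:
        for row in self.rows:
            if row.species == species:
                return row
        return None


@dataclass
class PromoterAlignment:
    """A promoter restricted to its five-species alignment columns.

    Columns are ordered in promoter orientation (5'->3' of the promoter);
    for '-' strand promoters characters are complemented and order reversed.
    ``columns[i]`` holds one character per focal species (None = species
    missing at that position), ``ref_chars[i]`` the reference base and
    ``ref_positions[i]`` its genomic coordinate.
    """

    promoter: PromoterRegion
    species: tuple[str, ...]
    columns: list[tuple[Optional[str], ...]] = field(default_factory=list)
    ref_positions: list[int] = field(default_factory=list)
    ref_chars: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class PutativeCisElement:
    """A >= 6-nt fully conserved run, in promoter (sense) orientation."""

    sequence: str
    ref_interval: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_ELEMENT_LENGTH:
            raise ValueError("putative cis-element shorter than minimum length")
        if any(c not in _BASES for c in self.sequence.upper()):
            raise ValueError("element sequence contains gap/ambiguous characters")

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_promoter_alignment(
    blocks: Iterable[AlignmentBlock],
    promoter: PromoterRegion,
    focal_species: Sequence[str] = DEFAULT_FOCAL_SPECIES,
) -> PromoterAlignment:
    """Restrict alignment blocks to the unmasked positions of a promoter.

    Returns one column per reference position that is covered by a block and
    not coding-masked; reference-gap columns are dropped. Zero coverage
    yields a valid empty alignment.
    """
    region = promoter.region
    unmasked = promoter.unmasked_intervals()

    def is_wanted(pos: int) -> bool:
        return any(iv.start <= pos < iv.end for iv in unmasked)

    covered: dict[int, tuple[tuple[Optional[str], ...], str]] = {}
    n_duplicate = 0
    for block in blocks:
        ref = block.ref_row
        if ref.chrom != region.chrom:
            continue
        if ref.strand != "+":
            raise ValueError("reference rows must be on the + strand")
        if ref.start >= region.end or ref.start + ref.size <= region.start:
            continue
        species_rows = [block.row_for(sp) for sp in focal_species]
        pos = ref.start
        for j, c in enumerate(ref.text):
            if c == "-":
                continue
            if region.start <= pos < region.end and is_wanted(pos):
                if pos in covered:
                    n_duplicate += 1
                else:
                    chars = tuple(
                        row.text[j] if row is not None else None for row in species_rows
                    )
                    covered[pos] = (chars, c)
            pos += 1

    if n_duplicate:
        logger.warning(
            "%d positions in promoter %s covered by multiple blocks; first block wins",
            n_duplicate,
            promoter.owner_id or str(region),
        )

    pa = PromoterAlignment(promoter=promoter, species=tuple(focal_species))
    positions = sorted(covered)
    if region.strand == "-":
        positions.reverse()
    for pos in positions:
        chars, ref_char = covered[pos]
        if region.strand == "-":
            chars = tuple(complement(c) if c is not None else None for c in chars)
            ref_char = complement(ref_char)
        pa.columns.append(chars)
        pa.ref_positions.append(pos)
        pa.ref_chars.append(ref_char)
    return pa


def is_conserved_column(column: Sequence[Optional[str]]) -> bool:
    """True iff all focal species are present, ungapped, unambiguous and identical."""
    if any(c is None for c in column):
        return False
    upper = [c.upper() for c in column]  # type: ignore[union-attr]
    if any(c not in _BASES for c in upper):
        return False
    return len(set(upper)) == 1


def count_conserved_columns(pa: PromoterAlignment) -> int:
    """Number of fully conserved columns; the conservation stratum statistic."""
    return sum(1 for col in pa.columns if is_conserved_column(col))


def conserved_runs(
    pa: PromoterAlignment, min_len: int = MIN_ELEMENT_LENGTH
) -> tuple[PutativeCisElement, ...]:
    """Maximal genomically contiguous runs of conserved columns, length >= min_len.

    A run breaks at any non-conserved column and at any gap in reference
    coordinates (uncovered, masked or reference-gap positions in between).
    """
    step = 1 if pa.promoter.region.strand == "+" else -1
    elements: list[PutativeCisElement] = []
    run_start: Optional[int] = None  # column index

    def close(run_end: int) -> None:
        # run covers column indices [run_start, run_end)
        if run_start is None or run_end - run_start < min_len:
            return
        seq = "".join(pa.ref_chars[run_start:run_end]).upper()
        positions = pa.ref_positions[run_start:run_end]
        iv = GenomicInterval(
            pa.promoter.region.chrom,
            min(positions),
            max(positions) + 1,
            pa.promoter.region.strand,
        )
        elements.append(PutativeCisElement(sequence=seq, ref_interval=iv))

    prev_pos: Optional[int] = None
    for i, col in enumerate(pa.columns):
        conserved = is_conserved_column(col)
        contiguous = prev_pos is not None and pa.ref_positions[i] == prev_pos + step
        if conserved and run_start is not None and contiguous:
            pass  # run continues
        elif conserved:
            close(i)
            run_start = i
        else:
            close(i)
            run_start = None
        prev_pos = pa.ref_positions[i]
    close(len(pa.columns))
    return tuple(elements)


def relative_position(pa: PromoterAlignment, genomic_pos: int) -> int:
    """Position of a column relative to the promoter anchor (+1 = anchor)."""
    anchor = pa.promoter.anchor
    if anchor is None:
        raise ValueError("promoter has no anchor coordinate")
    if pa.promoter.region.strand == "+":
        return genomic_pos - anchor
    return anchor - genomic_pos


def conservation_profile(
    pas: Iterable[PromoterAlignment], window: int = 1
) -> pd.Series:
    """Mean percent identity per anchor-relative position, window-smoothed.

    For each promoter, conservation flags are indexed by position relative to
    the promoter anchor (TSS or pre-miRNA 5' end); the profile value at
    position r is the mean over promoters of the fraction of conserved
    columns inside the centered window [r - window//2, r + window//2].
    Positions with no data in any promoter are absent.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_promoter: list[pd.Series] = []
    for pa in pas:
        if not pa.columns:
            continue
        rels = [relative_position(pa, p) for p in pa.ref_positions]
        flags = pd.Series(
            [1.0 if is_conserved_column(c) else 0.0 for c in pa.columns], index=rels
        ).sort_index()
        if window > 1:
            # reindex to a dense axis so the window is genomic, not positional
            dense = flags.reindex(range(flags.index.min(), flags.index.max() + 1))
            smoothed = dense.rolling(window=window, center=True, min_periods=1).mean()
            smoothed = smoothed.loc[flags.index]
        else:
            smoothed = flags
        per_promoter.append(smoothed)
    if not per_promoter:
        return pd.Series(dtype=float)
    frame = pd.concat(per_promoter, axis=1)
    return frame.mean(axis=1, skipna=True) * 100.0
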
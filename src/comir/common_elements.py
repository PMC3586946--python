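"""Common cis-elements between two promoters and their length spectrum.

A common cis-element is a distinct string of >= 6 nt that occurs in some
putative element of promoter A and in some putative element of promoter B,
and that is maximal: it is not a substring of a longer string that is also
common to both sides. Counting distinct maximal strings (rather than
occurrences) keeps the per-length statistic from being mechanically inflated
by a single long shared run, which would otherwise contribute a match at
every shorter length.

Matching is exact, case-insensitive and sense-strand only.

The implementation extends exact matches along diagonals of a numpy match
matrix over the two element sets (every maximal common string equals some
maximal diagonal run), then applies a global substring-maximality filter.
Tests hold it to a brute-force substring-intersection oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .conservation import MIN_ELEMENT_LENGTH, PutativeCisElement

ElementLike = Union[PutativeCisElement, str]


@dataclass(frozen=True)
class CommonCisElement:
    """A maximal shared string with its witness occurrences on each side.

    Witnesses are ``(element_index, offset)`` pairs into the input element
    sequences (uppercased), one list per promoter.
    """

    sequence: str
    occurrences_a: tuple[tuple[int, int], ...]
    occurrences_b: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthSpectrum:
    """Per-length counts of maximal common cis-elements; absent length = 0."""

    counts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if any(length < MIN_ELEMENT_LENGTH for length, _ in self.counts):
            raise ValueError("spectrum lengths must be >= minimum element length")

    def as_dict(self) -> dict[int, int]:
        return dict(self.counts)

    def count(self, length: int) -> int:
        return self.as_dict().get(length, 0)

    def lengths_observed(self) -> tuple[int, ...]:
        return tuple(sorted(length for length, n in self.counts if n >= 1))

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)


def _sequences(elements: Iterable[ElementLike]) -> list[str]:
    out = []
    for el in elements:
        seq = el.sequence if isinstance(el, PutativeCisElement) else el
        out.append(seq.upper())
    return out


def _maximal_match_runs(seqs_a: Sequence[str], seqs_b: Sequence[str], min_len: int) -> set[str]:
    """Strings of all maximal exact diagonal matches of length >= min_len.

    The element sets are joined with distinct sentinel bytes that never match
    anything, so one match-length DP over the joined strings covers every
    element pair without runs crossing element boundaries.
    """
    if not seqs_a or not seqs_b:
        return set()
    x = "\x01".join(seqs_a)
    y = "\x02".join(seqs_b)
    if len(x) < min_len or len(y) < min_len:
        return set()
    ax = np.frombuffer(x.encode("latin1"), dtype=np.uint8)
    ay = np.frombuffer(y.encode("latin1"), dtype=np.uint8)
    eq = ax[:, None] == ay[None, :]
    n, m = eq.shape
    # match-run length ending at (i, j) along the diagonal
    length = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n):
        length[i + 1, 1:] = np.where(eq[i], length[i, :-1] + 1, 0)
    run_end = length[1:, 1:] >= min_len
    continues = np.zeros_like(eq)
    continues[:-1, :-1] = eq[1:, 1:]
    run_end &= ~continues
    runs: set[str] = set()
    for i, j in zip(*np.nonzero(run_end)):
        run_len = int(length[i + 1, j + 1])
        runs.add(x[i - run_len + 1 : i + 1])
    return runs


def find_common_elements(
    a: Sequence[ElementLike],
    b: Sequence[ElementLike],
    min_len: int = MIN_ELEMENT_LENGTH,
) -> tuple[CommonCisElement, ...]:
    """All maximal strings of length >= min_len shared by the two element sets.

    Returns each distinct string s such that s is a substring of some element
    of ``a`` and of some element of ``b`` and s is not contained in another
    returned string. Output is sorted by (descending length, sequence) for
    deterministic downstream files.
    """
    seqs_a = _sequences(a)
    seqs_b = _sequences(b)
    candidates = _maximal_match_runs(seqs_a, seqs_b, min_len)
    maximal = _filter_maximal(candidates)
    out = []
    for seq in sorted(maximal, key=lambda s: (-len(s), s)):
        out.append(
            CommonCisElement(
                sequence=seq,
                occurrences_a=_occurrences(seq, seqs_a),
                occurrences_b=_occurrences(seq, seqs_b),
            )
        )
    return tuple(out)


def _filter_maximal(candidates: set[str]) -> set[str]:
    by_len = sorted(candidates, key=len, reverse=True)
    kept: list[str] = []
    out: set[str] = set()
    for s in by_len:
        if any(s in t for t in kept if len(t) > len(s)):
            continue
        kept.append(s)
        out.add(s)
    return out


def _occurrences(needle: str, haystacks: Sequence[str]) -> tuple[tuple[int, int], ...]:
    occ = []
    for idx, hay in enumerate(haystacks):
        start = hay.find(needle)
        while start != -1:
            occ.append((idx, start))
            start = hay.find(needle, start + 1)
    return tuple(occ)


def length_spectrum(common: Iterable[CommonCisElement]) -> LengthSpectrum:
    """Tabulate distinct common strings per length."""
    counts: dict[int, int] = {}
    for el in common:
        counts[el.length] = counts.get(el.length, 0) + 1
    return LengthSpectrum(counts=tuple(sorted(counts.items())))


def pair_spectrum(
    a: Sequence[ElementLike], b: Sequence[ElementLike], min_len: int = MIN_ELEMENT_LENGTH
) -> LengthSpectrum:
    """Length spectrum of the maximal common elements of one promoter pair."""
    return length_spectrum(find_common_elements(a, b, min_len=min_len))
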
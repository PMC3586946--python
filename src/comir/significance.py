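"""Empirical resampling null for common-element counts, and significance calls.

The chance incidence of common cis-elements between two unrelated promoters
is estimated by sampling pairs of background promoters — one from a pool
matched to the conservation level of miRNA promoters, one from a pool
matched to target-gene promoters — and recording the per-length counts of
maximal common elements for each sampled pair (100,000 pairs by default).
An observed promoter pair is then tested per length with the add-one
permutation p-value and Bonferroni correction across the lengths observed;
the pair is called significant when any corrected p-value is <= alpha
(default 0.05).

Conservation matching uses decile strata of the conserved-column count
relative to a background population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .common_elements import LengthSpectrum, pair_spectrum
from .conservation import MIN_ELEMENT_LENGTH, PutativeCisElement

DEFAULT_N_PAIRS = 100_000
DEFAULT_ALPHA = 0.05
DEFAULT_N_STRATA = 10


@dataclass(frozen=True)
class PoolPromoter:
    """A background promoter reduced to what the null needs: its putative
    elements and its conserved-column count."""

    member_id: str
    elements: tuple[PutativeCisElement, ...]
    conserved_columns: int


@dataclass(frozen=True)
class BackgroundPool:
    """A conservation-matched set of background promoters."""

    members: tuple[PoolPromoter, ...]
    descriptor: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("background pool must be non-empty")

    def filter_stratum(
        self, stratum: int, background_counts: Sequence[int], n_strata: int = DEFAULT_N_STRATA
    ) -> "BackgroundPool":
        """Members whose conserved-column count falls in the given stratum."""
        kept = tuple(
            m
            for m in self.members
            if conservation_stratum(m.conserved_columns, background_counts, n_strata) == stratum
        )
        if not kept:
            raise ValueError(f"no pool members in stratum {stratum}")
        return BackgroundPool(members=kept, descriptor=f"{self.descriptor}|stratum={stratum}")


def conservation_stratum(
    conserved_columns: int,
    background_counts: Sequence[int],
    n_strata: int = DEFAULT_N_STRATA,
) -> int:
    """Quantile stratum (1..n_strata) of a conserved-column count.

    Stratum k covers counts between the (k-1)/n and k/n quantiles of the
    background population; counts outside the population range clamp to the
    first/last stratum.
    """
    counts = np.asarray(list(background_counts))
    if counts.size == 0:
        raise ValueError("background population is empty")
    edges = np.quantile(counts, np.linspace(0, 1, n_strata + 1)[1:-1])
    stratum = int(np.searchsorted(edges, conserved_columns, side="left")) + 1
    return min(max(stratum, 1), n_strata)


@dataclass
class NullDistribution:
    """Per-length empirical distributions of chance common-element counts.

    ``histograms[L]`` maps a count value N to the number of sampled pairs
    whose spectrum had N maximal common elements of length L; pairs with no
    such element are the implicit mass at N = 0.
    """

    histograms: dict[int, dict[int, int]]
    n_pairs: int
    seed: int
    descriptor_a: str = ""
    descriptor_b: str = ""

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")

    def tail_count(self, length: int, n_obs: int) -> int:
        """Number of null pairs with N(length) >= n_obs."""
        if n_obs <= 0:
            return self.n_pairs
        hist = self.histograms.get(length, {})
        return sum(pairs for count, pairs in hist.items() if count >= n_obs)

    def pmf(self, length: int) -> dict[int, float]:
        hist = dict(self.histograms.get(length, {}))
        hist[0] = self.n_pairs - sum(v for k, v in hist.items() if k != 0)
        return {count: pairs / self.n_pairs for count, pairs in sorted(hist.items())}

    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.histograms))

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"length": length, "count": count, "n_pairs": pairs}
            for length, hist in sorted(self.histograms.items())
            for count, pairs in sorted(hist.items())
        ]
        return pd.DataFrame(rows, columns=["length", "count", "n_pairs"])

    def save(self, tsv_path: str | Path, header_path: Optional[str | Path] = None) -> None:
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        header = {
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "descriptor_a": self.descriptor_a,
            "descriptor_b": self.descriptor_b,
        }
        header_path = (
            Path(header_path) if header_path is not None else tsv_path.with_suffix(".json")
        )
        header_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(
        cls, tsv_path: str | Path, header_path: Optional[str | Path] = None
    ) -> "NullDistribution":
        tsv_path = Path(tsv_path)
        frame = pd.read_csv(tsv_path, sep="\t")
        header_path = (
            Path(header_path) if header_path is not None else tsv_path.with_suffix(".json")
        )
        header = json.loads(header_path.read_text())
        histograms: dict[int, dict[int, int]] = {}
        for length, count, pairs in frame[["length", "count", "n_pairs"]].to_numpy():
            histograms.setdefault(int(length), {})[int(count)] = int(pairs)
        return cls(
            histograms=histograms,
            n_pairs=int(header["n_pairs"]),
            seed=int(header["seed"]),
            descriptor_a=header.get("descriptor_a", ""),
            descriptor_b=header.get("descriptor_b", ""),
        )


def build_null(
    pool_a: BackgroundPool,
    pool_b: BackgroundPool,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    min_len: int = MIN_ELEMENT_LENGTH,
) -> NullDistribution:
    """Sample random background promoter pairs and tabulate chance spectra.

    Pairs draw one member from each pool, uniformly with replacement; a draw
    that pairs a member with itself (possible when the pools share members)
    is redrawn. Spectra are cached per member pair, so repeated draws of the
    same pair cost nothing. Reproducible for a given seed.
    """
    if (
        len(pool_a.members) == 1
        and len(pool_b.members) == 1
        and pool_a.members[0].member_id == pool_b.members[0].member_id
    ):
        raise ValueError("no valid pair: both pools contain only the same member")
    rng = np.random.default_rng(seed)
    ids_a = [m.member_id for m in pool_a.members]
    ids_b = [m.member_id for m in pool_b.members]
    cache: dict[tuple[str, str], LengthSpectrum] = {}
    histograms: dict[int, dict[int, int]] = {}
    for _ in range(n_pairs):
        while True:
            i = int(rng.integers(len(ids_a)))
            j = int(rng.integers(len(ids_b)))
            if ids_a[i] != ids_b[j]:
                break
        key = (ids_a[i], ids_b[j])
        spectrum = cache.get(key)
        if spectrum is None:
            spectrum = pair_spectrum(
                pool_a.members[i].elements, pool_b.members[j].elements, min_len=min_len
            )
            cache[key] = spectrum
        for length, count in spectrum.counts:
            if count >= 1:
                hist = histograms.setdefault(length, {})
                hist[count] = hist.get(count, 0) + 1
    return NullDistribution(
        histograms=histograms,
        n_pairs=n_pairs,
        seed=seed,
        descriptor_a=pool_a.descriptor,
        descriptor_b=pool_b.descriptor,
    )


def empirical_p(null: NullDistribution, length: int, n_obs: int) -> float:
    """Add-one permutation p-value for observing >= n_obs elements of a length.

    p = (#{null pairs with N(L) >= n_obs} + 1) / (n_pairs + 1); never exactly
    zero, as is standard for resampling p-values.
    """
    if length < MIN_ELEMENT_LENGTH:
        raise ValueError(f"length must be >= {MIN_ELEMENT_LENGTH}")
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return (null.tail_count(length, n_obs) + 1) / (null.n_pairs + 1)


@dataclass(frozen=True)
class LengthTest:
    length: int
    n_obs: int
    p_raw: float
    p_corrected: float


@dataclass(frozen=True)
class SignificanceResult:
    """Per-length Bonferroni-corrected tests for one promoter pair."""

    tests: tuple[LengthTest, ...]
    m: int
    alpha: float
    significant: bool

    @property
    def min_corrected_p(self) -> float:
        return min((t.p_corrected for t in self.tests), default=1.0)


def test_significance(
    spectrum: LengthSpectrum,
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    test_all_lengths: bool = False,
) -> SignificanceResult:
    """Bonferroni-corrected per-length test of an observed spectrum.

    By default m counts only the lengths actually observed (N_obs >= 1); with
    ``test_all_lengths`` m spans every length from the minimum up to the
    largest length seen in the null or the observation. An empty spectrum is
    never significant (m = 0).
    """
    observed = spectrum.lengths_observed()
    if test_all_lengths:
        upper = max((*null.lengths(), *observed), default=MIN_ELEMENT_LENGTH - 1)
        m = max(0, upper - MIN_ELEMENT_LENGTH + 1)
    else:
        m = len(observed)
    tests = []
    for length in observed:
        p_raw = empirical_p(null, length, spectrum.count(length))
        tests.append(
            LengthTest(
                length=length,
                n_obs=spectrum.count(length),
                p_raw=p_raw,
                p_corrected=min(1.0, m * p_raw),
            )
        )
    significant = any(t.p_corrected <= alpha for t in tests)
    return SignificanceResult(tests=tuple(tests), m=m, alpha=alpha, significant=significant)
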
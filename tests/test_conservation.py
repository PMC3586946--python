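import numpy as np
import pandas as pd
import pytest

from comir import (
    AlignmentBlock,
    AlignmentRow,
    GenomicInterval,
    PromoterAlignment,
    PromoterRegion,
    conservation_profile,
    conserved_runs,
    count_conserved_columns,
    extract_promoter_alignment,
    is_conserved_column,
)
from comir.intervals import reverse_complement

from .oracles import scan_conserved_runs

SPECIES = ("human", "chimp", "mouse", "rat", "dog")


def block_from_texts(texts, ref_start=0, chrom="chr1", species=SPECIES):
    rows = tuple(
        AlignmentRow(
            species=sp,
            chrom=chrom if sp == species[0] else f"chr_{sp}",
            start=ref_start,
            size=sum(1 for c in t if c != "-"),
            strand="+",
            src_size=10_000_000,
            text=t,
        )
        for sp, t in zip(species, texts)
    )
    return AlignmentBlock(rows=rows, ref_species=species[0])


def promoter(start, end, strand="+", masked=(), chrom="chr1", anchor=None):
    return PromoterRegion(
        region=GenomicInterval(chrom, start, end, strand),
        masked=tuple(GenomicInterval(chrom, s, e, strand) for s, e in masked),
        owner_id="p",
        anchor=anchor,
    )


class TestIsConservedColumn:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (("A", "A", "A", "A", "A"), True),
            (("a", "A", "a", "A", "a"), True),  # soft-masked ok
            (("A", "A", "A", "A", "G"), False),
            (("A", "A", "A", "A", None), False),  # species missing from block
            (("A", "A", "-", "A", "A"), False),
            (("N", "N", "N", "N", "N"), False),
        ],
    )
    def test_cases(self, column, expected):
        assert is_conserved_column(column) is expected


class TestExtraction:
    def test_identity_extraction(self):
        text = "ACGTACGTAA"
        block = block_from_texts([text] * 5, ref_start=100)
        pa = extract_promoter_alignment([block], promoter(100, 110))
        assert len(pa) == 10
        assert pa.ref_positions == list(range(100, 110))
        assert "".join(pa.ref_chars) == text

    def test_mask_subtraction(self):
        block = block_from_texts(["ACGTACGTAA"] * 5, ref_start=100)
        pa = extract_promoter_alignment([block], promoter(100, 110, masked=[(103, 105)]))
        assert len(pa) == 8
        assert 103 not in pa.ref_positions and 104 not in pa.ref_positions

    def test_reference_gap_columns_dropped(self):
        texts = ["ACG--TACGT", "ACGGGTACGT", "ACG--TACGT", "ACGAATACGT", "ACG--TACGT"]
        block = block_from_texts(texts, ref_start=0)
        pa = extract_promoter_alignment([block], promoter(0, 8))
        assert len(pa) == 8
        assert "".join(pa.ref_chars) == "ACGTACGT"

    def test_minus_strand_equals_revcomp_of_plus(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            length = 30
            texts = []
            base = "".join(rng.choice(list("ACGT"), length))
            for s in range(5):
                chars = list(base)
                for i in rng.choice(length, 6, replace=False):
                    chars[i] = rng.choice(list("ACGT-"))
                texts.append("".join(chars))
            texts[0] = base  # reference ungapped
            block = block_from_texts(texts, ref_start=500)
            plus = extract_promoter_alignment([block], promoter(500, 500 + length, "+"))
            minus = extract_promoter_alignment([block], promoter(500, 500 + length, "-"))
            assert "".join(minus.ref_chars) == reverse_complement("".join(plus.ref_chars))
            assert minus.ref_positions == plus.ref_positions[::-1]
            for col_m, col_p in zip(minus.columns, reversed(plus.columns)):
                assert [is_conserved_column(col_m)] == [is_conserved_column(col_p)]

    def test_zero_coverage_is_valid_empty(self):
        block = block_from_texts(["ACGTACGTAA"] * 5, ref_start=100)
        pa = extract_promoter_alignment([block], promoter(5000, 5100))
        assert len(pa) == 0
        assert count_conserved_columns(pa) == 0


class TestCounting:
    def test_counts_conserved_columns(self):
        texts = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAACAAAAA", "AAAAAAAAAA", "AAAAAAGAAA"]
        block = block_from_texts(texts)
        pa = extract_promoter_alignment([block], promoter(0, 10))
        assert count_conserved_columns(pa) == 8

    def test_iid_columns_match_binomial_rate(self, rng):
        # per-column conservation probability p -> empirical fraction ~ p
        p, n = 0.3, 5000
        conserved = rng.random(n) < p
        texts = []
        base = rng.choice(list("ACGT"), n)
        for s in range(5):
            chars = base.copy()
            if s > 0:
                for i in np.flatnonzero(~conserved):
                    if rng.random() < 0.7:
                        chars[i] = rng.choice([c for c in "ACGT" if c != base[i]])
            texts.append("".join(chars))
        pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, n))
        frac = count_conserved_columns(pa) / n
        # conserved columns >= planted p; mutation misses add a little
        assert frac == pytest.approx(np.mean(conserved), abs=0.05)


class TestConservedRuns:
    def test_terminal_divergence_trims_run(self):
        texts = ["ACGTACGTAA"] * 5
        texts[2] = "ACGTACGTCC"  # mouse diverges at last two columns
        texts[3] = "ACGTACGTGG"  # rat too
        pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, 10))
        runs = conserved_runs(pa)
        assert [(r.sequence, r.ref_interval.start, r.ref_interval.end) for r in runs] == [
            ("ACGTACGT", 0, 8)
        ]

    def test_five_column_run_is_below_threshold(self):
        texts = ["ACGTAG"] * 5
        texts[1] = "ACGTAC"  # divergence at column 5 leaves a 5-run
        pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, 6))
        assert conserved_runs(pa) == ()

    def test_interrupted_run_splits_into_two_elements(self):
        base = "A" * 14
        texts = [base] * 5
        texts[4] = "A" * 7 + "C" + "A" * 6  # dog diverges at column 7
        pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, 14))
        runs = conserved_runs(pa)
        assert sorted(r.length for r in runs) == [6, 7]

    def test_mask_breaks_runs(self):
        texts = ["A" * 20] * 5
        pa = extract_promoter_alignment(
            [block_from_texts(texts)], promoter(0, 20, masked=[(9, 11)])
        )
        runs = conserved_runs(pa)
        assert sorted(r.length for r in runs) == [9, 9]

    def test_block_split_at_boundary_is_invariant(self):
        texts = ["ACGTACGTACGTACGTACGT"] * 5
        whole = block_from_texts(texts, ref_start=0)
        left = block_from_texts([t[:12] for t in texts], ref_start=0)
        right = block_from_texts([t[12:] for t in texts], ref_start=12)
        p = promoter(0, 20)
        runs_whole = conserved_runs(extract_promoter_alignment([whole], p))
        runs_split = conserved_runs(extract_promoter_alignment([left, right], p))
        assert runs_whole == runs_split

    def test_total_element_length_bounded_by_conserved_count(self, rng):
        for _ in range(20):
            n = 60
            conserved = rng.random(n) < 0.6
            base = rng.choice(list("ACGT"), n)
            texts = []
            for s in range(5):
                chars = base.copy()
                if s == 1:
                    for i in np.flatnonzero(~conserved):
                        chars[i] = rng.choice([c for c in "ACGT" if c != base[i]])
                texts.append("".join(chars))
            pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, n))
            runs = conserved_runs(pa)
            assert sum(r.length for r in runs) <= count_conserved_columns(pa)

    def test_element_sequences_match_reference_genome(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 200))
        texts = [genome] * 5
        texts[3] = "".join(
            c if rng.random() < 0.7 else rng.choice(list("ACGT")) for c in genome
        )
        pa = extract_promoter_alignment([block_from_texts(texts)], promoter(0, 200))
        for el in conserved_runs(pa):
            assert el.sequence == genome[el.ref_interval.start : el.ref_interval.end]

    def test_matches_column_scan_oracle_on_random_alignments(self, rng):
        for _ in range(50):
            pa = random_promoter_alignment(rng)
            got = [
                (r.sequence, r.ref_interval.start, r.ref_interval.end)
                for r in conserved_runs(pa)
            ]
            expect = scan_conserved_runs(
                pa.columns, pa.ref_positions, pa.ref_chars, pa.promoter.region.strand
            )
            assert got == expect


def random_promoter_alignment(rng, length=80):
    """Random column records with missing species, gaps, skips and both strands."""
    strand = "+" if rng.random() < 0.5 else "-"
    region = PromoterRegion(GenomicInterval("c", 1000, 1000 + length, strand), owner_id="q")
    positions = sorted(int(p) for p in rng.choice(length, size=int(length * 0.8), replace=False))
    positions = [1000 + p for p in positions]
    if strand == "-":
        positions = positions[::-1]
    pa = PromoterAlignment(promoter=region, species=SPECIES)
    for pos in positions:
        ref = str(rng.choice(list("ACGT")))
        if rng.random() < 0.55:
            col = tuple([ref] * 5)
        else:
            col = tuple(
                str(rng.choice(list("ACGT-N"))) if rng.random() < 0.8 else None
                for _ in range(5)
            )
        pa.columns.append(col)
        pa.ref_positions.append(pos)
        pa.ref_chars.append(ref)
    return pa


class TestProfile:
    def make_pa(self, flags, anchor=0, start=1000):
        n = len(flags)
        region = PromoterRegion(
            GenomicInterval("c", start, start + n, "+"), owner_id="p", anchor=anchor
        )
        pa = PromoterAlignment(promoter=region, species=SPECIES)
        for i, f in enumerate(flags):
            base = "A"
            pa.columns.append(("A",) * 5 if f else ("A", "A", "A", "A", "C"))
            pa.ref_positions.append(start + i)
            pa.ref_chars.append(base)
        return pa

    def test_fully_conserved_profile_is_100(self):
        prof = conservation_profile([self.make_pa([1] * 10)], window=3)
        assert np.allclose(prof.values, 100.0)

    def test_mean_of_two_promoters(self):
        prof = conservation_profile(
            [self.make_pa([1] * 10), self.make_pa([0] * 10)], window=1
        )
        assert np.allclose(prof.values, 50.0)

    def test_no_coverage_gives_empty_profile(self):
        assert conservation_profile([], window=5).empty

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            conservation_profile([self.make_pa([1] * 10)], window=0)

    def test_positions_are_anchor_relative(self):
        prof = conservation_profile([self.make_pa([1] * 10, anchor=1005)], window=1)
        assert list(prof.index) == list(range(-5, 5))
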
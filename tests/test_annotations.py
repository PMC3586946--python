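import pytest

from comir import (
    GeneModel,
    GenomicInterval,
    MatureMirna,
    MirnaClassification,
    PreMirna,
    PromoterRegion,
    TssRecord,
    assign_mature_to_pre,
    classify_mirna,
    cluster_intergenic,
    mask_coding,
    promoter_for_gene,
    promoter_for_mirna,
    select_tss,
)
from comir.intervals import merge_intervals, subtract_intervals

from .oracles import brute_force_clusters


def pre(mirna_id, start, end, strand="+", chrom="chr1", seq=None):
    return PreMirna(mirna_id, GenomicInterval(chrom, start, end, strand), sequence=seq)


def gene(gene_id, start, end, strand="+", chrom="chr1", cds=()):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), tuple(cds))


class TestIntervals:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_subtract_intervals_matches_setwise_oracle(self, rng):
        for _ in range(50):
            region = GenomicInterval("c", 0, 100)
            holes = [
                GenomicInterval("c", int(s), int(s) + int(l) + 1)
                for s, l in zip(rng.integers(0, 99, 5), rng.integers(0, 30, 5))
            ]
            got = subtract_intervals(region, holes)
            covered = set()
            for h in holes:
                covered |= set(range(max(0, h.start), min(100, h.end)))
            expect = sorted(set(range(100)) - covered)
            got_positions = sorted(
                p for iv in got for p in range(iv.start, iv.end)
            )
            assert got_positions == expect


class TestMatureAssignment:
    MATURE = "AUGCAUGCAUGCAUGCAUGCA"
    DNA = "ATGCATGCATGCATGCATGCA"

    def test_exact_containment(self):
        m = MatureMirna("miR-X", self.MATURE)
        p = pre("mir-X", 0, 80, seq="GG" + self.DNA + "CCTT")
        assert assign_mature_to_pre(m, [p]).assigned_pre == {"mir-X"}

    def test_no_subsequence_no_assignment(self):
        m = MatureMirna("miR-X", self.MATURE)
        p = pre("mir-Y", 0, 80, seq="GGCC" * 20)
        assert assign_mature_to_pre(m, [p]).assigned_pre == frozenset()

    def test_paralogous_pres_both_assigned(self):
        m = MatureMirna("miR-X", self.MATURE)
        pres = [
            pre("mir-X-1", 0, 80, seq="AA" + self.DNA),
            pre("mir-X-2", 100, 180, seq=self.DNA + "TT"),
        ]
        assert assign_mature_to_pre(m, pres).assigned_pre == {"mir-X-1", "mir-X-2"}

    def test_name_stem_gate_blocks_unrelated_pre(self):
        m = MatureMirna("hsa-miR-17-5p", self.MATURE)
        unrelated = pre("hsa-mir-99", 0, 80, seq=self.DNA)
        related = pre("hsa-mir-17-2", 0, 80, seq=self.DNA)
        assigned = assign_mature_to_pre(m, [unrelated, related]).assigned_pre
        assert assigned == {"hsa-mir-17-2"}


class TestClassification:
    def test_contained_same_strand_is_intragenic(self):
        host = gene("g", 0, 50_000)
        cls = classify_mirna(pre("m", 1000, 1100), [host])
        assert cls.kind == "intragenic" and cls.host is host

    def test_opposite_strand_is_intergenic(self):
        host = gene("g", 0, 50_000, strand="-")
        assert classify_mirna(pre("m", 1000, 1100), [host]).kind == "intergenic"

    def test_override_forces_intergenic(self):
        host = gene("g", 0, 50_000)
        cls = classify_mirna(pre("m", 1000, 1100), [host], override_intergenic=["m"])
        assert cls.kind == "intergenic" and cls.host is None

    def test_gene_order_does_not_change_host(self):
        tss = {
            "a": [TssRecord("a", "chr1", 0, "+", 5, "primary_tss_db")],
            "b": [TssRecord("b", "chr1", 0, "+", 50, "primary_tss_db")],
        }
        genes = [gene("a", 0, 5000), gene("b", 500, 6000)]
        m = pre("m", 1000, 1080)
        host1 = classify_mirna(m, genes, tss_records=tss).host
        host2 = classify_mirna(m, list(reversed(genes)), tss_records=tss).host
        assert host1.gene_id == host2.gene_id == "b"  # strongest TSS support


class TestSelectTss:
    def test_maximal_confident_cdna_count_wins(self):
        recs = [
            TssRecord("g", "chr1", 100, "+", 10, "primary_tss_db"),
            TssRecord("g", "chr1", 300, "+", 4, "primary_tss_db"),
        ]
        assert select_tss("g", recs).position == 100

    def test_weak_primary_falls_back_to_most_upstream(self):
        recs = [
            TssRecord("g", "chr1", 100, "+", 3, "primary_tss_db"),
            TssRecord("g", "chr1", 500, "+", 0, "refseq"),
            TssRecord("g", "chr1", 800, "+", 0, "ucsc_genes"),
        ]
        picked = select_tss("g", recs)
        assert picked.position == 500 and picked.source == "refseq"

    def test_fallback_is_strand_aware(self):
        recs = [
            TssRecord("g", "chr1", 100, "-", 2, "primary_tss_db"),
            TssRecord("g", "chr1", 500, "-", 0, "refseq"),
            TssRecord("g", "chr1", 800, "-", 0, "ucsc_genes"),
        ]
        assert select_tss("g", recs).position == 800  # most upstream on '-'

    def test_singleton_returned(self):
        rec = TssRecord("g", "chr1", 42, "+", 1, "primary_tss_db")
        assert select_tss("g", [rec]) is rec

    def test_missing_gene_errors(self):
        with pytest.raises(ValueError):
            select_tss("g", [])


class TestClustering:
    def test_small_gap_joins_cluster_head_is_most_upstream(self):
        pres = [pre("a", 10_000, 10_080), pre("b", 14_080, 14_160)]
        clusters = cluster_intergenic(pres)  # gap 4,000
        assert len(clusters) == 1
        assert clusters[0].head.mirna_id == "a"

    def test_large_gap_splits(self):
        pres = [pre("a", 10_000, 10_080), pre("b", 16_080, 16_160)]  # gap 6,000
        assert len(cluster_intergenic(pres)) == 2

    def test_chaining_three_loci(self):
        pres = [
            pre("a", 10_000, 10_080),
            pre("b", 14_080, 14_160),  # gap 4,000
            pre("c", 18_660, 18_740),  # gap 4,500
        ]
        clusters = cluster_intergenic(pres)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_minus_strand_head_is_rightmost(self):
        pres = [pre("a", 10_000, 10_080, "-"), pre("b", 12_000, 12_080, "-")]
        assert cluster_intergenic(pres)[0].head.mirna_id == "b"

    def test_matches_single_linkage_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            starts = sorted(int(s) for s in rng.integers(0, 200_000, n))
            pres = [pre(f"m{i}", s, s + int(rng.integers(60, 120))) for i, s in enumerate(starts)]
            got = sorted(
                frozenset(int(m.mirna_id[1:]) for m in c.members)
                for c in cluster_intergenic(pres)
            )
            expect = brute_force_clusters([(p.locus.start, p.locus.end) for p in pres], 5000)
            assert got == expect


class TestPromoterArithmetic:
    def test_intragenic_plus_strand_window(self):
        tss = TssRecord("g", "chr1", 10_000, "+", 9, "primary_tss_db")
        region = promoter_for_mirna(
            pre("m", 12_000, 12_080), MirnaClassification("intragenic", gene("g", 9000, 30_000)), tss=tss
        ).region
        assert (region.start, region.end) == (8000, 10_200)

    def test_intragenic_minus_strand_mirror(self):
        tss = TssRecord("g", "chr1", 10_000, "-", 9, "primary_tss_db")
        region = promoter_for_mirna(
            pre("m", 8000, 8080, "-"),
            MirnaClassification("intragenic", gene("g", 1000, 10_000, "-")),
            tss=tss,
        ).region
        assert (region.start, region.end) == (9800, 12_000)

    def test_intergenic_upstream_window(self):
        p = promoter_for_mirna(pre("m", 50_000, 50_080), MirnaClassification("intergenic"))
        assert (p.region.start, p.region.end) == (47_800, 50_000)
        assert p.anchor == 50_000

    def test_gene_promoter_windows(self):
        g = gene("g", 5000, 20_000)
        plus = promoter_for_gene(g, TssRecord("g", "chr1", 5000, "+", 9, "primary_tss_db"))
        assert (plus.region.start, plus.region.end) == (3000, 5200)
        minus = promoter_for_gene(
            gene("g", 1000, 5000, "-"), TssRecord("g", "chr1", 5000, "-", 9, "primary_tss_db")
        )
        assert (minus.region.start, minus.region.end) == (4800, 7000)

    def test_chromosome_start_clip(self):
        g = gene("g", 1000, 9000)
        p = promoter_for_gene(g, TssRecord("g", "chr1", 1000, "+", 9, "primary_tss_db"))
        assert (p.region.start, p.region.end) == (0, 1200)

    def test_unclipped_length_is_2200_for_every_origin(self):
        tss = TssRecord("g", "chr1", 10_000, "+", 9, "primary_tss_db")
        intragenic = promoter_for_mirna(
            pre("m", 12_000, 12_080), MirnaClassification("intragenic", gene("g", 9000, 30_000)), tss=tss
        )
        intergenic = promoter_for_mirna(pre("m", 50_000, 50_080), MirnaClassification("intergenic"))
        g = promoter_for_gene(gene("g", 9000, 30_000), tss)
        assert {p.region.length for p in (intragenic, intergenic, g)} == {2200}


class TestMaskCoding:
    def promoter(self):
        return PromoterRegion(GenomicInterval("chr1", 0, 2200), owner_id="p")

    def test_single_overlap(self):
        g = gene("g", 0, 3000, cds=[GenomicInterval("chr1", 100, 200)])
        masked = mask_coding(self.promoter(), [g])
        assert [(iv.start, iv.end) for iv in masked.masked] == [(100, 200)]
        assert masked.unmasked_length == 2100

    def test_cds_clipped_to_promoter(self):
        g = gene("g", 2000, 3000, cds=[GenomicInterval("chr1", 2100, 3000)])
        masked = mask_coding(self.promoter(), [g])
        assert [(iv.start, iv.end) for iv in masked.masked] == [(2100, 2200)]

    def test_overlapping_cds_merge(self):
        g1 = gene("g1", 0, 3000, cds=[GenomicInterval("chr1", 100, 200)])
        g2 = gene("g2", 0, 3000, cds=[GenomicInterval("chr1", 150, 300)])
        masked = mask_coding(self.promoter(), [g1, g2])
        assert [(iv.start, iv.end) for iv in masked.masked] == [(100, 300)]

    def test_opposite_strand_cds_still_masks(self):
        g = gene("g", 0, 3000, strand="-", cds=[GenomicInterval("chr1", 100, 200, "-")])
        assert mask_coding(self.promoter(), [g]).unmasked_length == 2100

    def test_idempotent_and_monotone(self):
        g1 = gene("g1", 0, 3000, cds=[GenomicInterval("chr1", 100, 200)])
        once = mask_coding(self.promoter(), [g1])
        assert mask_coding(once, [g1]) == once
        g2 = gene("g2", 0, 3000, cds=[GenomicInterval("chr1", 500, 700)])
        more = mask_coding(once, [g2])
        assert more.unmasked_length <= once.unmasked_length

    def test_fully_masked_promoter_is_valid(self):
        g = gene("g", 0, 3000, cds=[GenomicInterval("chr1", 0, 2500)])
        assert mask_coding(self.promoter(), [g]).unmasked_length == 0


def test_merge_intervals_handles_abutting_and_nested():
    ivs = [
        GenomicInterval("c", 0, 10),
        GenomicInterval("c", 10, 20),
        GenomicInterval("c", 5, 8),
        GenomicInterval("c", 30, 40),
    ]
    merged = merge_intervals(ivs)
    assert [(iv.start, iv.end) for iv in merged] == [(0, 20), (30, 40)]
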
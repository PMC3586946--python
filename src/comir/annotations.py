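"""Gene/miRNA/TSS annotations, miRNA classification and promoter determination.

Promoters follow the classic host-gene convention: intragenic miRNAs inherit
the promoter of the host gene they sit in (same strand), taken as the
[-2000, +200) window around the host TSS; intergenic miRNAs get the 2,200-bp
window upstream of the pre-miRNA 5' end, with polycistronic clusters
(inter-locus gaps <= 5,000 bp) sharing the promoter of the 5'-most member.
Coding intervals overlapping a promoter are masked out before any element
search.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200
PROMOTER_LENGTH = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
CLUSTER_MAX_GAP = 5000
TSS_CDNA_FALLBACK_MAX = 3

PRIMARY_TSS_SOURCE = "primary_tss_db"
FALLBACK_TSS_SOURCES = ("refseq", "ucsc_genes")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: its span plus coding (CDS) intervals."""

    gene_id: str
    span: GenomicInterval
    cds: tuple[GenomicInterval, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        for iv in self.cds:
            if not (self.span.contains(iv) and iv.strand == self.span.strand):
                raise ValueError(
                    f"CDS {iv} of gene {self.gene_id} not contained in span on same strand"
                )
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda iv: (iv.start, iv.end)))
        )


@dataclass(frozen=True)
class TssRecord:
    """One reported transcription start site with its cDNA support."""

    gene_id: str
    chrom: str
    position: int
    strand: str
    confident_cdna_count: int
    source: str

    def __post_init__(self) -> None:
        if self.confident_cdna_count < 0:
            raise ValueError("confident_cdna_count must be >= 0")


@dataclass(frozen=True)
class PreMirna:
    """A pre-miRNA hairpin locus; ``sequence`` (DNA) enables mature assignment."""

    mirna_id: str
    locus: GenomicInterval
    mature_ids: frozenset[str] = frozenset()
    sequence: Optional[str] = None


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA (RNA alphabet) with its assigned pre-miRNA hairpins."""

    mature_id: str
    sequence: str
    assigned_pre: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("mature sequence must be non-empty")


@dataclass(frozen=True)
class PromoterRegion:
    """A determined promoter with coding subintervals masked out.

    ``anchor`` is the genomic coordinate of the +1 position (the host TSS, or
    the pre-miRNA 5' end for intergenic promoters); it anchors relative
    coordinates in conservation profiles.
    """

    region: GenomicInterval
    masked: tuple[GenomicInterval, ...] = ()
    origin: str = "intragenic_host_tss"  # or intergenic_upstream, cluster_head
    owner_id: str = ""
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        last_end = None
        for iv in self.masked:
            if not self.region.contains(iv):
                raise ValueError(f"masked interval {iv} outside promoter {self.region}")
            if last_end is not None and iv.start < last_end:
                raise ValueError("masked intervals must be sorted and non-overlapping")
            last_end = iv.end

    @property
    def unmasked_length(self) -> int:
        return self.region.length - sum(iv.length for iv in self.masked)

    def unmasked_intervals(self) -> tuple[GenomicInterval, ...]:
        return subtract_intervals(self.region, self.masked)


@dataclass(frozen=True)
class MirnaClassification:
    kind: str  # "intragenic" | "intergenic"
    host: Optional[GeneModel] = None


@dataclass(frozen=True)
class MirnaCluster:
    members: tuple[PreMirna, ...]
    head: PreMirna


# ---------------------------------------------------------------------------
# mature -> pre assignment
# ---------------------------------------------------------------------------

_ARM_SUFFIX = re.compile(r"[-.](5p|3p|as|s)$|\*$", re.IGNORECASE)
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-", re.IGNORECASE)
_FAMILY_PREFIX = re.compile(r"^(mir|let|lin)-?", re.IGNORECASE)


def name_stem(name: str) -> str:
    """Family stem of a miRNA name: species prefix, mir/let prefix and
    arm suffixes stripped, lowercased. ``hsa-miR-17-5p`` -> ``17``."""
    stem = name.strip().lower()
    stem = _SPECIES_PREFIX.sub("", stem)
    stem = _ARM_SUFFIX.sub("", stem)
    stem = _FAMILY_PREFIX.sub("", stem)
    return stem


def _stems_compatible(mature_stem: str, pre_stem: str) -> bool:
    # A pre named with a trailing numeric paralog suffix (mir-17-1, mir-17-2)
    # still matches mature miR-17.
    if mature_stem == pre_stem:
        return True
    return bool(re.fullmatch(re.escape(mature_stem) + r"-\d+", pre_stem))


def assign_mature_to_pre(mature: MatureMirna, pres: Iterable[PreMirna]) -> MatureMirna:
    """Assign a mature miRNA to every pre-miRNA hairpin that carries it.

    A pre-miRNA qualifies when its sequence contains the mature sequence
    (T/U-insensitive, case-insensitive) and its name shares the mature name's
    family stem. An empty assignment is a valid result, flagged for
    downstream discard.
    """
    mature_dna = mature.sequence.upper().replace("U", "T")
    mature_stem = name_stem(mature.mature_id)
    assigned = set()
    for pre in pres:
        if pre.sequence is None:
            continue
        pre_dna = pre.sequence.upper().replace("U", "T")
        if mature_dna in pre_dna and _stems_compatible(mature_stem, name_stem(pre.mirna_id)):
            assigned.add(pre.mirna_id)
    return replace(mature, assigned_pre=frozenset(assigned))


# ---------------------------------------------------------------------------
# classification and clustering
# ---------------------------------------------------------------------------

def _best_tss_count(gene_id: str, tss_records: Optional[Mapping[str, Sequence[TssRecord]]]) -> int:
    if not tss_records or gene_id not in tss_records:
        return 0
    return max(r.confident_cdna_count for r in tss_records[gene_id])


def classify_mirna(
    pre: PreMirna,
    genes: Iterable[GeneModel],
    override_intergenic: Iterable[str] = (),
    tss_records: Optional[Mapping[str, Sequence[TssRecord]]] = None,
) -> MirnaClassification:
    """Classify a pre-miRNA as intragenic (inside a same-strand host gene)
    or intergenic.

    Any same-strand overlap with a gene span makes the miRNA intragenic,
    unless its id is on the intergenic override list (miRNAs whose overlap
    with a host is too marginal to trust). Among several candidate hosts the
    one with the strongest TSS support (highest confident-cDNA count) wins,
    ties broken by gene_id.
    """
    if pre.mirna_id in set(override_intergenic):
        return MirnaClassification("intergenic")
    hosts = [g for g in genes if g.span.overlaps(pre.locus, same_strand=True)]
    if not hosts:
        return MirnaClassification("intergenic")
    if len(hosts) > 1:
        logger.info(
            "pre-miRNA %s overlaps %d same-strand genes; picking strongest-TSS host",
            pre.mirna_id,
            len(hosts),
        )
        hosts.sort(key=lambda g: (-_best_tss_count(g.gene_id, tss_records), g.gene_id))
    return MirnaClassification("intragenic", host=hosts[0])


def _upstream_key(record: TssRecord) -> int:
    # smaller = more 5'/upstream in gene orientation
    return record.position if record.strand == "+" else -record.position


def select_tss(gene_id: str, records: Iterable[TssRecord]) -> TssRecord:
    """Select the representative TSS for a gene.

    The primary-database record with maximal confident-cDNA count is used;
    when that maximum is weak (<= 3 cDNAs) the most upstream TSS reported by
    RefSeq or UCSC Genes is adopted instead. Count ties break by most
    upstream position, then lexicographic source.
    """
    recs = [r for r in records if r.gene_id == gene_id]
    if not recs:
        raise ValueError(f"no TSS record for gene {gene_id}")
    primary = [r for r in recs if r.source == PRIMARY_TSS_SOURCE]
    if primary:
        best_count = max(r.confident_cdna_count for r in primary)
        if best_count > TSS_CDNA_FALLBACK_MAX:
            candidates = [r for r in primary if r.confident_cdna_count == best_count]
            return min(candidates, key=lambda r: (_upstream_key(r), r.source))
        fallback = [r for r in recs if r.source in FALLBACK_TSS_SOURCES]
        if fallback:
            return min(fallback, key=lambda r: (_upstream_key(r), r.source))
        # weakly supported primary TSS but nothing else reported
        return min(primary, key=lambda r: (-r.confident_cdna_count, _upstream_key(r), r.source))
    fallback = [r for r in recs if r.source in FALLBACK_TSS_SOURCES]
    if fallback:
        return min(fallback, key=lambda r: (_upstream_key(r), r.source))
    return min(recs, key=lambda r: (-r.confident_cdna_count, _upstream_key(r), r.source))


def cluster_intergenic(
    pres: Iterable[PreMirna], max_gap: int = CLUSTER_MAX_GAP
) -> tuple[MirnaCluster, ...]:
    """Chain intergenic pre-miRNAs into polycistronic clusters.

    Single-linkage on the same chromosome and strand: consecutive loci whose
    closest-end gap is <= ``max_gap`` join one cluster. The cluster head is
    the 5'-most member in strand orientation; its upstream window serves as
    the shared promoter of the polycistron.
    """
    by_group: dict[tuple[str, str], list[PreMirna]] = {}
    for pre in pres:
        by_group.setdefault((pre.locus.chrom, pre.locus.strand), []).append(pre)

    clusters: list[MirnaCluster] = []
    for (_, strand), members in sorted(by_group.items()):
        members.sort(key=lambda p: (p.locus.start, p.locus.end, p.mirna_id))
        current: list[PreMirna] = []
        reach = None  # rightmost end seen in the open cluster
        for pre in members:
            if current and pre.locus.start - reach <= max_gap:
                current.append(pre)
                reach = max(reach, pre.locus.end)
            else:
                if current:
                    clusters.append(_finish_cluster(current, strand))
                current = [pre]
                reach = pre.locus.end
        if current:
            clusters.append(_finish_cluster(current, strand))
    return tuple(clusters)


def _finish_cluster(members: list[PreMirna], strand: str) -> MirnaCluster:
    if strand == "+":
        head = min(members, key=lambda p: (p.locus.start, p.mirna_id))
    else:
        head = max(members, key=lambda p: (p.locus.end, p.mirna_id))
    return MirnaCluster(members=tuple(members), head=head)


# ---------------------------------------------------------------------------
# promoter determination
# ---------------------------------------------------------------------------

def _tss_window(chrom: str, position: int, strand: str, chrom_length: Optional[int]) -> GenomicInterval:
    if strand == "+":
        start, end = position - PROMOTER_UPSTREAM, position + PROMOTER_DOWNSTREAM
    else:
        start, end = position - PROMOTER_DOWNSTREAM, position + PROMOTER_UPSTREAM
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(f"promoter window around TSS {position}{strand} is empty after clipping")
    return GenomicInterval(chrom, start, end, strand)


def promoter_for_gene(
    gene: GeneModel, tss: TssRecord, chrom_length: Optional[int] = None
) -> PromoterRegion:
    """[-2000, +200) window (strand-aware) around the selected gene TSS."""
    region = _tss_window(tss.chrom, tss.position, tss.strand, chrom_length)
    return PromoterRegion(
        region=region, origin="intragenic_host_tss", owner_id=gene.gene_id, anchor=tss.position
    )


def promoter_for_mirna(
    pre: PreMirna,
    classification: MirnaClassification,
    tss: Optional[TssRecord] = None,
    cluster_head: Optional[PreMirna] = None,
    chrom_length: Optional[int] = None,
) -> PromoterRegion:
    """Promoter of a pre-miRNA.

    Intragenic: the host gene's [-2000, +200) TSS window (``tss`` required).
    Intergenic: the 2,200-bp window upstream of the pre-miRNA 5' end, taken
    from the cluster head when the miRNA is part of a polycistronic cluster.
    Windows are clipped at chromosome boundaries; a window that clips to
    nothing is an error.
    """
    if classification.kind == "intragenic":
        if tss is None:
            raise ValueError(f"intragenic miRNA {pre.mirna_id} requires a host TSS")
        region = _tss_window(tss.chrom, tss.position, tss.strand, chrom_length)
        return PromoterRegion(
            region=region,
            origin="intragenic_host_tss",
            owner_id=pre.mirna_id,
            anchor=tss.position,
        )
    source = cluster_head if cluster_head is not None else pre
    locus = source.locus
    origin = "cluster_head" if cluster_head is not None else "intergenic_upstream"
    if locus.strand == "+":
        start, end = locus.start - PROMOTER_LENGTH, locus.start
    else:
        start, end = locus.end, locus.end + PROMOTER_LENGTH
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(f"intergenic promoter for {pre.mirna_id} is empty after clipping")
    region = GenomicInterval(locus.chrom, start, end, locus.strand)
    return PromoterRegion(
        region=region, origin=origin, owner_id=pre.mirna_id, anchor=locus.five_prime
    )


def mask_coding(promoter: PromoterRegion, genes: Iterable[GeneModel]) -> PromoterRegion:
    """Mask every coding (CDS) interval overlapping the promoter, either strand.

    Overlapping coding intervals are merged; masking is idempotent. A fully
    masked promoter is valid (it simply yields no elements).
    """
    overlaps = []
    for gene in genes:
        for cds in gene.cds:
            clipped = promoter.region.intersect(cds)
            if clipped is not None:
                overlaps.append(clipped)
    overlaps.extend(promoter.masked)
    masked = merge_intervals(overlaps)
    return replace(promoter, masked=masked)


def build_cds_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over CDS intervals for fast masking."""
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        for cds in gene.cds:
            trees.setdefault(cds.chrom, IntervalTree()).addi(cds.start, cds.end, gene.gene_id)
    return trees


def mask_coding_indexed(promoter: PromoterRegion, cds_index: Mapping[str, IntervalTree]) -> PromoterRegion:
    """Like :func:`mask_coding` but against a prebuilt CDS interval tree."""
    tree = cds_index.get(promoter.region.chrom)
    if tree is None:
        return promoter
    hits = tree.overlap(promoter.region.start, promoter.region.end)
    overlaps = [
        GenomicInterval(
            promoter.region.chrom,
            max(h.begin, promoter.region.start),
            min(h.end, promoter.region.end),
            promoter.region.strand,
        )
        for h in hits
    ]
    overlaps.extend(promoter.masked)
    return replace(promoter, masked=merge_intervals(overlaps))
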
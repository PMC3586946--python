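"""End-to-end orchestration: annotations -> promoters -> elements -> predictions.

These functions wire the module layers together the way the command-line
interface and the worked examples use them; each step remains individually
importable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotations import (
    GeneModel,
    MatureMirna,
    PreMirna,
    PromoterRegion,
    TssRecord,
    classify_mirna,
    cluster_intergenic,
    mask_coding_indexed,
    build_cds_index,
    promoter_for_gene,
    promoter_for_mirna,
    select_tss,
)
from .conservation import (
    DEFAULT_FOCAL_SPECIES,
    AlignmentBlock,
    PutativeCisElement,
    conserved_runs,
    count_conserved_columns,
    extract_promoter_alignment,
)
from .prediction import (
    PredictionRecord,
    PredictionResources,
    predict_targets,
    predictions_frame,
)
from .significance import NullDistribution


@dataclass
class PromoterSet:
    """Determined promoters: one per gene, one per miRNA promoter owner.

    Clustered intergenic pre-miRNAs share their cluster head's promoter;
    ``pre_owner`` maps every pre-miRNA id to the id owning its promoter.
    """

    gene_promoters: dict[str, PromoterRegion]
    mirna_promoters: dict[str, PromoterRegion]
    pre_owner: dict[str, str]
    unevaluated_genes: tuple[str, ...] = ()

    def all_promoters(self) -> dict[str, PromoterRegion]:
        merged = dict(self.gene_promoters)
        merged.update(self.mirna_promoters)
        return merged


def determine_promoters(
    genes: Sequence[GeneModel],
    pres: Sequence[PreMirna],
    tss_records: Sequence[TssRecord],
    override_intergenic: Iterable[str] = (),
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> PromoterSet:
    """Resolve every promoter: gene TSS windows, host-TSS windows for
    intragenic miRNAs, upstream windows for intergenic clusters; coding
    regions masked everywhere."""
    tss_by_gene: dict[str, list[TssRecord]] = {}
    for rec in tss_records:
        tss_by_gene.setdefault(rec.gene_id, []).append(rec)
    cds_index = build_cds_index(genes)

    def chrom_len(chrom: str) -> Optional[int]:
        return chrom_lengths.get(chrom) if chrom_lengths else None

    gene_promoters: dict[str, PromoterRegion] = {}
    unevaluated = []
    for gene in genes:
        if gene.gene_id not in tss_by_gene:
            unevaluated.append(gene.gene_id)
            continue
        tss = select_tss(gene.gene_id, tss_by_gene[gene.gene_id])
        promoter = promoter_for_gene(gene, tss, chrom_length=chrom_len(tss.chrom))
        gene_promoters[gene.gene_id] = mask_coding_indexed(promoter, cds_index)

    mirna_promoters: dict[str, PromoterRegion] = {}
    pre_owner: dict[str, str] = {}
    intergenic: list[PreMirna] = []
    for pre in pres:
        cls = classify_mirna(pre, genes, override_intergenic, tss_records=tss_by_gene)
        if cls.kind == "intragenic":
            host = cls.host
            assert host is not None
            tss = select_tss(host.gene_id, tss_by_gene[host.gene_id])
            promoter = promoter_for_mirna(
                pre, cls, tss=tss, chrom_length=chrom_len(tss.chrom)
            )
            mirna_promoters[pre.mirna_id] = mask_coding_indexed(promoter, cds_index)
            pre_owner[pre.mirna_id] = pre.mirna_id
        else:
            intergenic.append(pre)

    for cluster in cluster_intergenic(intergenic):
        head = cluster.head
        promoter = promoter_for_mirna(
            head,
            classification=classify_mirna(head, (), override_intergenic),
            cluster_head=head if len(cluster.members) > 1 else None,
            chrom_length=chrom_len(head.locus.chrom),
        )
        mirna_promoters[head.mirna_id] = mask_coding_indexed(promoter, cds_index)
        for member in cluster.members:
            pre_owner[member.mirna_id] = head.mirna_id

    return PromoterSet(
        gene_promoters=gene_promoters,
        mirna_promoters=mirna_promoters,
        pre_owner=pre_owner,
        unevaluated_genes=tuple(unevaluated),
    )


def extract_elements(
    promoters: Mapping[str, PromoterRegion],
    blocks: Sequence[AlignmentBlock],
    focal_species: Sequence[str] = DEFAULT_FOCAL_SPECIES,
    min_len: int = 6,
) -> tuple[dict[str, tuple[PutativeCisElement, ...]], dict[str, int]]:
    """Putative elements and conserved-column counts for each promoter."""
    elements: dict[str, tuple[PutativeCisElement, ...]] = {}
    conserved_counts: dict[str, int] = {}
    for owner in sorted(promoters):
        pa = extract_promoter_alignment(blocks, promoters[owner], focal_species)
        elements[owner] = conserved_runs(pa, min_len=min_len)
        conserved_counts[owner] = count_conserved_columns(pa)
    return elements, conserved_counts


def predict_all(
    matures: Sequence[MatureMirna],
    gene_ids: Sequence[str],
    promoter_set: PromoterSet,
    elements: Mapping[str, tuple[PutativeCisElement, ...]],
    null: NullDistribution,
    alpha: float = 0.05,
    min_len: int = 6,
) -> tuple[tuple[PredictionRecord, ...], pd.DataFrame]:
    """Run the target scan for every assignable mature miRNA.

    Matures without an assigned pre-miRNA are skipped (discarded upstream by
    construction); each pre-miRNA uses its promoter owner's elements, so
    clustered miRNAs share their polycistron head's promoter.
    """
    pre_elements = {
        pre_id: elements[owner]
        for pre_id, owner in promoter_set.pre_owner.items()
        if owner in elements
    }
    gene_elements = {g: elements[g] for g in gene_ids if g in elements}
    resources = PredictionResources(
        pre_elements=pre_elements,
        gene_elements=gene_elements,
        null=null,
        alpha=alpha,
        min_len=min_len,
    )
    records: list[PredictionRecord] = []
    for mature in sorted(matures, key=lambda m: m.mature_id):
        if not mature.assigned_pre:
            continue
        records.extend(predict_targets(mature, gene_ids, resources))
    return tuple(records), predictions_frame(records)
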
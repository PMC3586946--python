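"""Readers and writers for the package's file formats.

Genomic coordinates are 0-based half-open in memory (BED-native); the GFF3
reader converts from 1-based closed coordinates. Alignments go through
Biopython's MAF support; FASTA through Bio.SeqIO; tables through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import GeneModel, MatureMirna, PreMirna, PromoterRegion, TssRecord
from .conservation import AlignmentBlock, AlignmentRow, PutativeCisElement
from .intervals import GenomicInterval

TSS_COLUMNS = ["gene_id", "chrom", "position", "strand", "confident_cdna_count", "source"]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_premirnas_bed6(
    bed_path: str | Path, fasta_path: Optional[str | Path] = None
) -> tuple[PreMirna, ...]:
    """Pre-miRNA loci from BED6, optionally with hairpin sequences from FASTA."""
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    pres = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, name, _score, strand = line.split("\t")[:6]
        pres.append(
            PreMirna(
                mirna_id=name,
                locus=GenomicInterval(chrom, int(start), int(end), strand),
                sequence=seqs.get(name),
            )
        )
    return tuple(pres)


def write_premirnas_bed6(pres: Iterable[PreMirna], bed_path: str | Path) -> None:
    lines = [
        f"{p.locus.chrom}\t{p.locus.start}\t{p.locus.end}\t{p.mirna_id}\t0\t{p.locus.strand}"
        for p in sorted(pres, key=lambda p: (p.locus.chrom, p.locus.start, p.mirna_id))
    ]
    Path(bed_path).write_text("\n".join(lines) + "\n" if lines else "")


def read_genes_bed12(path: str | Path) -> tuple[GeneModel, ...]:
    """Gene models from BED12; CDS = blocks intersected with the thick region."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end, name, _score, strand = fields[:6]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        span = GenomicInterval(chrom, int(start), int(end), strand)
        cds = []
        for bsize, bstart in zip(block_sizes, block_starts):
            exon_start = span.start + bstart
            exon_end = exon_start + bsize
            cstart, cend = max(exon_start, thick_start), min(exon_end, thick_end)
            if cstart < cend:
                cds.append(GenomicInterval(chrom, cstart, cend, strand))
        genes.append(GeneModel(gene_id=name, span=span, cds=tuple(cds), source="bed12"))
    return tuple(genes)


def write_genes_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = []
    for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
        cds = sorted(g.cds, key=lambda iv: iv.start)
        if cds:
            thick_start, thick_end = cds[0].start, cds[-1].end
            sizes = ",".join(str(iv.length) for iv in cds)
            starts = ",".join(str(iv.start - g.span.start) for iv in cds)
            n = len(cds)
        else:
            thick_start = thick_end = g.span.start
            sizes, starts, n = str(g.span.length), "0", 1
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    g.span.chrom, g.span.start, g.span.end, g.gene_id, 0, g.span.strand,
                    thick_start, thick_end, "0,0,0", n, sizes, starts,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_genes_gff3(path: str | Path) -> tuple[GeneModel, ...]:
    """Gene models from GFF3 (1-based closed -> half-open); CDS features
    found via Parent chains define the coding intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = tuple(
            GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
            for c in sorted(db.children(gene, featuretype="CDS"), key=lambda c: c.start)
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                span=GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand),
                cds=cds,
                source="gff3",
            )
        )
    return tuple(genes)


def read_gene_models(path: str | Path) -> tuple[GeneModel, ...]:
    """Dispatch on extension: .bed -> BED12, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed12(path)


# ---------------------------------------------------------------------------
# FASTA / TSV
# ---------------------------------------------------------------------------

def read_mature_fasta(path: str | Path) -> tuple[MatureMirna, ...]:
    """Mature miRNAs from FASTA; T is normalized to U (RNA alphabet)."""
    matures = []
    for rec in SeqIO.parse(str(path), "fasta"):
        matures.append(
            MatureMirna(mature_id=rec.id, sequence=str(rec.seq).upper().replace("T", "U"))
        )
    return tuple(matures)


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(seq_records, str(path), "fasta")


def read_tss_table(path: str | Path) -> tuple[TssRecord, ...]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "source": str})
    return tuple(
        TssRecord(
            gene_id=str(row["gene_id"]),
            chrom=str(row["chrom"]),
            position=int(row["position"]),
            strand=str(row["strand"]),
            confident_cdna_count=int(row["confident_cdna_count"]),
            source=str(row["source"]),
        )
        for _, row in frame.iterrows()
    )


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "chrom": r.chrom,
                "position": r.position,
                "strand": r.strand,
                "confident_cdna_count": r.confident_cdna_count,
                "source": r.source,
            }
            for r in records
        ],
        columns=TSS_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# promoters and elements
# ---------------------------------------------------------------------------

def write_promoters(promoters: Mapping[str, PromoterRegion], out_dir: str | Path) -> None:
    """BED6 of promoter regions plus a TSV sidecar of masked subintervals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_lines = []
    mask_rows = []
    meta = {}
    for owner in sorted(promoters):
        p = promoters[owner]
        r = p.region
        bed_lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{owner}\t0\t{r.strand}")
        for iv in p.masked:
            mask_rows.append(
                {"owner_id": owner, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            )
        meta[owner] = {"origin": p.origin, "anchor": p.anchor}
    (out_dir / "promoters.bed").write_text("\n".join(bed_lines) + "\n" if bed_lines else "")
    pd.DataFrame(mask_rows, columns=["owner_id", "chrom", "start", "end"]).to_csv(
        out_dir / "masked.tsv", sep="\t", index=False
    )
    (out_dir / "promoters.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_promoters(out_dir: str | Path) -> dict[str, PromoterRegion]:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "promoters.json").read_text())
    masks = pd.read_csv(out_dir / "masked.tsv", sep="\t")
    promoters: dict[str, PromoterRegion] = {}
    for line in (out_dir / "promoters.bed").read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, owner, _score, strand = line.split("\t")[:6]
        region = GenomicInterval(chrom, int(start), int(end), strand)
        own_masks = masks[masks["owner_id"] == owner]
        masked = tuple(
            GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), strand)
            for _, row in own_masks.sort_values("start").iterrows()
        )
        info = meta.get(owner, {})
        anchor = info.get("anchor")
        promoters[owner] = PromoterRegion(
            region=region,
            masked=masked,
            origin=info.get("origin", "intragenic_host_tss"),
            owner_id=owner,
            anchor=int(anchor) if anchor is not None else None,
        )
    return promoters


def write_elements(
    elements_by_owner: Mapping[str, Sequence[PutativeCisElement]], out_dir: str | Path
) -> None:
    """Putative elements as BED6 (name = sequence) and FASTA (id = owner:index)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_lines = []
    fasta: dict[str, str] = {}
    for owner in sorted(elements_by_owner):
        for i, el in enumerate(elements_by_owner[owner]):
            iv = el.ref_interval
            bed_lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.sequence}\t0\t{iv.strand}")
            fasta[f"{owner}:{i}"] = el.sequence
    (out_dir / "elements.bed").write_text("\n".join(bed_lines) + "\n" if bed_lines else "")
    write_fasta(fasta, out_dir / "elements.fasta")


def read_elements_fasta(path: str | Path) -> dict[str, list[str]]:
    """Element sequences grouped by owner (from ``owner:index`` FASTA ids)."""
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        owner = rec.id.rsplit(":", 1)[0]
        out.setdefault(owner, []).append(str(rec.seq).upper())
    return out


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def read_maf(path: str | Path, ref_species: str) -> list[AlignmentBlock]:
    """Alignment blocks from MAF; species = the prefix before the first dot
    of each source name (``hg18.chr7`` -> species hg18, chrom chr7)."""
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in aln:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            rows.append(
                AlignmentRow(
                    species=species,
                    chrom=chrom or species,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if int(ann["strand"]) >= 0 else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        blocks.append(AlignmentBlock(rows=tuple(rows), ref_species=ref_species))
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    lines = ["##maf version=1 scoring=none", ""]
    for block in blocks:
        lines.append("a score=0.000000")
        for row in block.rows:
            src = f"{row.species}.{row.chrom}" if row.chrom != row.species else row.species
            lines.append(
                f"s {src} {row.start} {row.size} {row.strand} {row.src_size} {row.text}"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# misc tables
# ---------------------------------------------------------------------------

def read_known_pairs(path: str | Path) -> tuple[tuple[str, str], ...]:
    """(mature_id, gene_id) pairs from a two-column TSV (header optional)."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] in ("mature_id", "mirna"):
            continue
        pairs.append((fields[0], fields[1]))
    return tuple(pairs)


def read_gene_list(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
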
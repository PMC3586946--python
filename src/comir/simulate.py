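"""Synthetic genomes, TSS tables and 5-species promoter alignments.

The generator emulates the statistical structure of the real inputs — a
chromosome with protein-coding genes (spans + CDS exons), intragenic and
intergenic pre-miRNAs, alternative TSS records with confident-cDNA counts,
and 5-species promoter alignments with tunable column-wise conservation and
optionally planted fully conserved motifs shared between promoters — so the
whole pipeline is testable without any genome download.

Conservation is column-Bernoulli: each alignment column is independently
fully conserved with probability ``conservation_p`` (default 0.27, matching
the per-column conservation rate of mammalian 2,200-bp promoter alignments,
where 580-640 of 2,200 columns are typically conserved across human, chimp,
mouse, rat and dog); divergent columns mutate a random subset of the
non-human species and occasionally carry alignment gaps. There is no
tree-based substitution model and no positional autocorrelation beyond the
planted motifs.

Randomness policy: every entity draws from its own stream keyed by
``(seed, labels...)`` so regenerating one promoter never shifts another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotations import (
    GeneModel,
    MatureMirna,
    PreMirna,
    PromoterRegion,
    TssRecord,
    assign_mature_to_pre,
)
from .conservation import (
    DEFAULT_FOCAL_SPECIES,
    AlignmentBlock,
    AlignmentRow,
    MIN_ELEMENT_LENGTH,
)
from .intervals import GenomicInterval, reverse_complement
from .significance import BackgroundPool, PoolPromoter
from .conservation import PutativeCisElement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_SLOT = 30_000
GENE_SPAN = 20_000
FIRST_GENE_BASE = 10_000
PRE_MIRNA_LENGTH = 80


def rng_for(seed: int, *labels) -> np.random.Generator:
    """Independent, reproducible stream for one simulated entity."""
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(label).encode()) for label in labels]
    return np.random.default_rng(key)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    return BASES[idx].tobytes().decode()


@dataclass(frozen=True)
class PlantedMotif:
    """A fully conserved motif written into one or more promoters.

    ``offset`` is in promoter orientation (0 = promoter 5' end); None places
    the motif at a deterministic in-promoter position clear of coding masks.
    """

    sequence: str
    targets: tuple[str, ...]
    offset: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_ELEMENT_LENGTH:
            raise ValueError("planted motif must be >= minimum element length")
        if any(c not in "ACGT" for c in self.sequence.upper()):
            raise ValueError("planted motif must be plain DNA")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study; defaults define the test conditions."""

    seed: int = 0
    n_genes: int = 20
    n_intragenic: int = 2
    n_intergenic: int = 3
    intergenic_gaps: tuple[int, ...] = (4000, 20000)
    promoter_len: int = 2200
    conservation_p: float = 0.27
    planted_motifs: tuple[PlantedMotif, ...] = ()
    override_intergenic: tuple[str, ...] = ()
    chrom: str = "chrS"
    chrom_len: Optional[int] = None
    gc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.conservation_p <= 1.0:
            raise ValueError("conservation_p must be in [0, 1]")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.n_intragenic > self.n_genes:
            raise ValueError("more intragenic miRNAs than host genes")
        if self.promoter_len < MIN_ELEMENT_LENGTH:
            raise ValueError("promoter_len too short")

    @property
    def required_chrom_len(self) -> int:
        genes_end = FIRST_GENE_BASE + self.n_genes * GENE_SLOT
        zone = genes_end + 20_000
        for k in range(self.n_intergenic):
            gap = self.intergenic_gaps[k % len(self.intergenic_gaps)] if self.intergenic_gaps else 20_000
            zone += PRE_MIRNA_LENGTH + gap
        return zone + 30_000


@dataclass
class GenomeBundle:
    """Everything make_genome produces, as in-memory domain objects."""

    chrom: str
    chrom_len: int
    genes: tuple[GeneModel, ...]
    pre_mirnas: tuple[PreMirna, ...]
    matures: tuple[MatureMirna, ...]
    tss_records: tuple[TssRecord, ...]
    override_intergenic: tuple[str, ...] = ()


def make_genome(spec: FixtureSpec) -> GenomeBundle:
    """Deterministically lay out genes, miRNAs and TSS records on one chromosome.

    Intragenic pre-miRNAs sit inside the first hosts' intron (same strand);
    intergenic pre-miRNAs are chained with the spec's gap pattern so both
    clustered (gap <= 5,000) and solitary layouts occur. Every sixth gene
    gets only weakly supported primary TSS records (confident-cDNA count
    <= 3) plus RefSeq/UCSC records, so both TSS-selection branches run.
    """
    chrom_len = spec.chrom_len if spec.chrom_len is not None else spec.required_chrom_len
    if chrom_len < spec.required_chrom_len:
        raise ValueError(
            f"chromosome length {chrom_len} too short; need {spec.required_chrom_len}"
        )

    genes: list[GeneModel] = []
    tss_records: list[TssRecord] = []
    for i in range(spec.n_genes):
        gene_id = f"gene{i:03d}"
        base = FIRST_GENE_BASE + i * GENE_SLOT
        strand = "-" if i % 7 == 3 else "+"
        span = GenomicInterval(spec.chrom, base, base + GENE_SPAN, strand)
        if strand == "+":
            cds = (
                GenomicInterval(spec.chrom, base + 50, base + 170, strand),
                GenomicInterval(spec.chrom, base + 5000, base + 5600, strand),
            )
            tss_pos = span.start
            upstream = -1
        else:
            cds = (
                GenomicInterval(spec.chrom, span.end - 170, span.end - 50, strand),
                GenomicInterval(spec.chrom, span.end - 5600, span.end - 5000, strand),
            )
            tss_pos = span.end
            upstream = +1
        genes.append(GeneModel(gene_id=gene_id, span=span, cds=cds, source="synthetic"))

        grng = rng_for(spec.seed, "tss", gene_id)
        if i % 6 == 5:
            # weak primary support: fallback branch of TSS selection
            tss_records.append(
                TssRecord(gene_id, spec.chrom, tss_pos, strand, int(grng.integers(0, 4)), "primary_tss_db")
            )
            tss_records.append(
                TssRecord(gene_id, spec.chrom, tss_pos + 150 * upstream, strand, 0, "refseq")
            )
            tss_records.append(
                TssRecord(gene_id, spec.chrom, tss_pos + 80 * upstream, strand, 0, "ucsc_genes")
            )
        else:
            tss_records.append(
                TssRecord(gene_id, spec.chrom, tss_pos, strand, int(grng.integers(4, 61)), "primary_tss_db")
            )
            tss_records.append(
                TssRecord(gene_id, spec.chrom, tss_pos - 40 * upstream, strand, 0, "refseq")
            )

    pres: list[PreMirna] = []
    matures: list[MatureMirna] = []
    for j in range(spec.n_intragenic):
        host = genes[j]
        mirna_id = f"mir-ig{j + 1}"
        if host.span.strand == "+":
            locus = GenomicInterval(
                spec.chrom, host.span.start + 1000, host.span.start + 1000 + PRE_MIRNA_LENGTH, "+"
            )
        else:
            locus = GenomicInterval(
                spec.chrom, host.span.end - 1000 - PRE_MIRNA_LENGTH, host.span.end - 1000, "-"
            )
        pres.append(_make_pre(spec, mirna_id, locus))
        matures.append(_make_mature(spec, mirna_id, pres[-1]))

    zone = FIRST_GENE_BASE + spec.n_genes * GENE_SLOT + 20_000
    cursor = zone
    for k in range(spec.n_intergenic):
        mirna_id = f"mir-int{k + 1}"
        locus = GenomicInterval(spec.chrom, cursor, cursor + PRE_MIRNA_LENGTH, "+")
        pres.append(_make_pre(spec, mirna_id, locus))
        matures.append(_make_mature(spec, mirna_id, pres[-1]))
        gap = spec.intergenic_gaps[k % len(spec.intergenic_gaps)] if spec.intergenic_gaps else 20_000
        cursor += PRE_MIRNA_LENGTH + gap

    matures = [assign_mature_to_pre(m, pres) for m in matures]
    return GenomeBundle(
        chrom=spec.chrom,
        chrom_len=chrom_len,
        genes=tuple(genes),
        pre_mirnas=tuple(pres),
        matures=tuple(matures),
        tss_records=tuple(tss_records),
        override_intergenic=spec.override_intergenic,
    )


def _make_pre(spec: FixtureSpec, mirna_id: str, locus: GenomicInterval) -> PreMirna:
    rng = rng_for(spec.seed, "pre", mirna_id)
    seq = random_dna(rng, PRE_MIRNA_LENGTH, spec.gc)
    return PreMirna(
        mirna_id=mirna_id,
        locus=locus,
        mature_ids=frozenset({mirna_id.replace("mir-", "miR-")}),
        sequence=seq,
    )


def _make_mature(spec: FixtureSpec, mirna_id: str, pre: PreMirna) -> MatureMirna:
    mature_id = mirna_id.replace("mir-", "miR-")
    assert pre.sequence is not None
    mature_seq = pre.sequence[20:42].replace("T", "U")
    return MatureMirna(mature_id=mature_id, sequence=mature_seq)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _plant_offset(motif: PlantedMotif, index: int, promoter: PromoterRegion) -> int:
    if motif.offset is not None:
        return motif.offset
    # deterministic position in the upstream, never-masked part of the window
    return 300 + 97 * index


def _orientation_masked_indices(promoter: PromoterRegion) -> set[int]:
    """Promoter-orientation indices covered by coding masks."""
    region = promoter.region
    out: set[int] = set()
    for iv in promoter.masked:
        for pos in range(iv.start, iv.end):
            if region.strand == "+":
                out.add(pos - region.start)
            else:
                out.add(region.end - 1 - pos)
    return out


def simulate_promoter_alignment_arrays(
    rng: np.random.Generator,
    length: int,
    conservation_p: float,
    gc: float = 0.5,
    plants: Sequence[tuple[str, int]] = (),
    forbidden: Optional[set[int]] = None,
) -> tuple[str, np.ndarray]:
    """Human sequence and per-column conservation flags in promoter orientation.

    ``plants`` is a list of (motif, offset) overwritten into the sequence and
    forced conserved; offsets must avoid ``forbidden`` (masked) indices.
    """
    seq = np.frombuffer(random_dna(rng, length, gc).encode(), dtype=np.uint8).copy()
    conserved = rng.random(length) < conservation_p
    for motif, offset in plants:
        if offset < 0 or offset + len(motif) > length:
            raise ValueError(f"motif offset {offset} outside promoter of length {length}")
        if forbidden and any(i in forbidden for i in range(offset, offset + len(motif))):
            raise ValueError("planted motif overlaps a coding-masked interval")
        seq[offset : offset + len(motif)] = np.frombuffer(
            motif.upper().encode(), dtype=np.uint8
        )
        conserved[offset : offset + len(motif)] = True
    return seq.tobytes().decode(), conserved


def make_alignments(
    spec: FixtureSpec,
    promoters: Mapping[str, PromoterRegion],
    focal_species: Sequence[str] = DEFAULT_FOCAL_SPECIES,
    n_blocks: int = 2,
) -> list[AlignmentBlock]:
    """5-species alignment blocks covering each promoter.

    Non-planted columns are conserved with ``conservation_p``; divergent
    columns mutate one to four non-reference species (occasionally to a gap),
    and rare reference-gap (insertion) columns are added. Each promoter's
    alignment is split into ``n_blocks`` abutting blocks to exercise
    run-stitching across block boundaries.
    """
    ref_species = focal_species[0]
    blocks: list[AlignmentBlock] = []
    plants_by_owner: dict[str, list[tuple[str, int]]] = {}
    for idx, motif in enumerate(spec.planted_motifs):
        for owner in motif.targets:
            if owner not in promoters:
                raise ValueError(f"planted motif targets unknown promoter owner {owner!r}")
            offset = _plant_offset(motif, idx, promoters[owner])
            plants_by_owner.setdefault(owner, []).append((motif.sequence.upper(), offset))

    # owners can share a genomic region (an intragenic miRNA and its host
    # gene have the same promoter); each unique region is simulated once
    by_region: dict[tuple[str, int, int, str], list[str]] = {}
    for owner_id in sorted(promoters):
        r = promoters[owner_id].region
        by_region.setdefault((r.chrom, r.start, r.end, r.strand), []).append(owner_id)

    for region_key in sorted(by_region):
        owners = by_region[region_key]
        promoter = promoters[owners[0]]
        region = promoter.region
        rng = rng_for(spec.seed, "aln", *region_key)
        forbidden = _orientation_masked_indices(promoter)
        plants = [p for owner in owners for p in plants_by_owner.get(owner, ())]
        seq, conserved = simulate_promoter_alignment_arrays(
            rng,
            region.length,
            spec.conservation_p,
            spec.gc,
            plants=plants,
            forbidden=forbidden,
        )
        # convert promoter orientation -> genomic + strand
        if region.strand == "-":
            seq_plus = reverse_complement(seq)
            conserved_plus = conserved[::-1]
        else:
            seq_plus = seq
            conserved_plus = conserved

        texts = _species_texts(rng, seq_plus, conserved_plus, len(focal_species))
        cuts = np.linspace(0, region.length, n_blocks + 1).astype(int)
        for b in range(n_blocks):
            lo, hi = int(cuts[b]), int(cuts[b + 1])
            if lo == hi:
                continue
            blocks.append(
                _build_block(
                    spec, focal_species, ref_species, region, texts, lo, hi, rng
                )
            )
    return blocks


def _species_texts(
    rng: np.random.Generator, ref_seq: str, conserved: np.ndarray, n_species: int
) -> list[str]:
    length = len(ref_seq)
    arrays = [np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy() for _ in range(n_species)]
    for pos in np.flatnonzero(~conserved):
        k = int(rng.integers(1, n_species))  # 1..n-1 non-reference species mutate
        victims = 1 + rng.permutation(n_species - 1)[:k]
        for v in victims:
            if rng.random() < 0.05:
                arrays[v][pos] = ord("-")
            else:
                current = arrays[v][pos]
                choices = BASES[BASES != current]
                arrays[v][pos] = choices[int(rng.integers(len(choices)))]
    return [a.tobytes().decode() for a in arrays]


def _build_block(
    spec: FixtureSpec,
    focal_species: Sequence[str],
    ref_species: str,
    region: GenomicInterval,
    texts: list[str],
    lo: int,
    hi: int,
    rng: np.random.Generator,
) -> AlignmentBlock:
    sub = [t[lo:hi] for t in texts]
    # sprinkle reference-gap (insertion) columns
    cols = [list(chars) for chars in zip(*sub)]
    out_cols: list[list[str]] = []
    for col in cols:
        out_cols.append(col)
        if rng.random() < 0.005:
            ins = ["-"] + [
                chr(BASES[int(rng.integers(4))]) for _ in range(len(focal_species) - 1)
            ]
            out_cols.append(ins)
    final = ["".join(c) for c in zip(*out_cols)]
    rows = []
    for s, species in enumerate(focal_species):
        text = final[s]
        ungapped = sum(1 for c in text if c != "-")
        rows.append(
            AlignmentRow(
                species=species,
                chrom=region.chrom if species == ref_species else f"chr_{species}",
                start=region.start + lo,
                size=ungapped,
                strand="+",
                src_size=spec.required_chrom_len,
                text=text,
            )
        )
    return AlignmentBlock(rows=tuple(rows), ref_species=ref_species)


# ---------------------------------------------------------------------------
# background pools and query promoters (element-level fast path)
# ---------------------------------------------------------------------------

def elements_from_mask(
    seq: str, conserved: np.ndarray, chrom: str, min_len: int = MIN_ELEMENT_LENGTH
) -> tuple[PutativeCisElement, ...]:
    """Putative elements implied by a conservation mask over one sequence."""
    padded = np.concatenate(([False], conserved.astype(bool), [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    elements = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            elements.append(
                PutativeCisElement(
                    sequence=seq[s:e].upper(),
                    ref_interval=GenomicInterval(chrom, int(s) + 1_000, int(e) + 1_000, "+"),
                )
            )
    return tuple(elements)


def simulate_promoter_elements(
    rng: np.random.Generator,
    length: int,
    conservation_p: float,
    gc: float = 0.5,
    chrom: str = "bg",
    plants: Sequence[tuple[str, int]] = (),
) -> tuple[tuple[PutativeCisElement, ...], int]:
    """Elements and conserved-column count of one simulated promoter.

    Statistically identical to running the alignment generator plus element
    extraction, but skips materializing the five species rows; used for
    background pools and large resampling experiments.
    """
    seq, conserved = simulate_promoter_alignment_arrays(
        rng, length, conservation_p, gc, plants=plants
    )
    return elements_from_mask(seq, conserved, chrom), int(conserved.sum())


def make_null_pools(
    spec: FixtureSpec,
    n_promoters: int,
    labels: tuple[str, str] = ("bgA", "bgB"),
) -> tuple[BackgroundPool, BackgroundPool]:
    """Two i.i.d. background pools from the query promoter generator.

    Members are drawn from the same column-Bernoulli generator as query
    promoters but carry no planted motifs; stratum labels are computable
    from their conserved-column counts.
    """
    pools = []
    for label in labels:
        members = []
        for i in range(n_promoters):
            rng = rng_for(spec.seed, "pool", label, i)
            member_id = f"{label}-{i:05d}"
            elements, count = simulate_promoter_elements(
                rng, spec.promoter_len, spec.conservation_p, spec.gc, chrom=member_id
            )
            members.append(
                PoolPromoter(member_id=member_id, elements=elements, conserved_columns=count)
            )
        pools.append(BackgroundPool(members=tuple(members), descriptor=label))
    return pools[0], pools[1]
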
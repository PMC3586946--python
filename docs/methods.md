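# Methods

## The model

`comir` predicts miRNA targets from transcriptional co-regulation rather
than from 3'UTR binding sites. The premise: if a miRNA and a gene are driven
by common transcription factors, their promoters should share cis-elements.
The pipeline operationalizes this in four steps.

**1. Promoter determination.** Intragenic miRNAs (pre-miRNA locus
overlapping a gene span on the same strand) are assumed to be transcribed
with their host, so they inherit the host promoter: the window
`[TSS - 2000, TSS + 200)` in gene orientation (the mirror window
`[t - 200, t + 2000)` on the minus strand). Intergenic miRNAs get the
2,200-bp window upstream of the pre-miRNA 5' end; consecutive intergenic
miRNAs with closest-end gaps <= 5,000 bp are treated as one polycistron and
share the window of the 5'-most member. Candidate gene promoters use the
same TSS window. The representative TSS is the primary-database record with
the highest confident-cDNA count; when that maximum is weak (<= 3 cDNAs)
the most upstream RefSeq/UCSC TSS is adopted instead. Coding (CDS)
intervals on either strand are masked out of every promoter before element
search. A small configured list of miRNA ids can be forced intergenic when
their host overlap is too marginal to trust.

**2. Putative cis-elements.** From multi-species alignments restricted to
the promoter, every maximal run of >= 6 consecutive columns in which five
focal mammals (human, chimp, mouse, rat, dog) carry the identical ungapped
base becomes a putative cis-element. Runs must be genomically contiguous on
the reference: masked, uncovered and reference-gap positions break runs.
A species absent from a block makes its columns non-conserved
(conservative). Matching is case-insensitive, so soft-masked bases can be
part of elements.

**3. Common cis-elements.** For a (miRNA promoter, gene promoter) pair,
every distinct string of >= 6 nt that occurs in a putative element of each
side, and that is not a substring of a longer such string, is a common
cis-element. Counting distinct maximal strings keeps the statistic
well-behaved: without the maximality filter a single shared run of length L
would mechanically contribute a hit at every length 6..L. Matching is exact
and sense-strand only. The per-length counts N(L) form the pair's length
spectrum, the tested statistic.

**4. Significance.** The chance level of common elements is estimated by
resampling: two pools of background promoters — one matched to the
conservation level of miRNA promoters, one to gene promoters, using decile
strata of the conserved-column count — are paired at random (100,000 pairs
by default; with replacement, self-pairs excluded) and each pair's spectrum
is tabulated. For an observed pair, each observed length gets the add-one
permutation p-value `p(L) = (#{null pairs with N(L) >= N_obs(L)} + 1) /
(n_pairs + 1)`; Bonferroni correction multiplies by the number m of lengths
observed, and the pair is significant when any corrected p <= 0.05. A
mature miRNA assigned to several pre-miRNA hairpins predicts the union of
the targets of each hairpin.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| promoter window | -2000/+200 nt around TSS | the region scanned for elements |
| intergenic window | 2,200 nt upstream of pre-miRNA 5' end | proxy promoter when no TSS is known |
| cluster gap | 5,000 nt | max closest-end gap for polycistronic chaining |
| TSS fallback threshold | 3 confident cDNAs | below this the most upstream RefSeq/UCSC TSS is used |
| minimum element length | 6 nt | both for putative and common elements |
| null size `n_pairs` | 100,000 | resampling depth; tests use scaled-down nulls |
| strata | 10 deciles | conservation matching granularity |
| alpha | 0.05 | family-wise significance level after Bonferroni |

## The synthetic-data generator

`comir.simulate` emulates the statistical structure of the real inputs so
every stage is testable without downloads: a chromosome of genes with CDS
exons (one exon inside the promoter's +200 tail, so masking is always
exercised), intragenic pre-miRNAs in host introns, intergenic pre-miRNAs
chained with configurable gaps, TSS tables in which every sixth gene has
only weak primary support (both TSS-selection branches run), and 5-species
alignment blocks. Conservation is column-Bernoulli with default probability
0.27 per column, chosen to reproduce the conserved-column levels typical of
2,200-bp mammalian promoter alignments (roughly 580-640 of 2,200 columns);
divergent columns mutate one to four non-reference species and occasionally
carry gaps, and rare reference-gap (insertion) columns are added. Each
promoter's alignment is split into abutting blocks to exercise run
stitching. Planted motifs are written into chosen promoters as fully
conserved runs.

What the generator does **not** emulate: phylogenetic structure (no tree,
no branch lengths — divergent columns are exchangeable across species),
positional autocorrelation of conservation (real promoters have conserved
blocks, not i.i.d. columns), compositional heterogeneity (uniform base
usage; a GC knob exists but defaults to 0.5), and repeats. Tests passing on
these fixtures therefore demonstrate correctness of the algorithms and
calibration of the resampling test under the stated conditions, not
performance on real genomes — where clustered conservation makes chance
common elements more frequent and the empirical null correspondingly
heavier.

Randomness is keyed per entity (`(seed, labels...)` -> independent
generator streams), so regenerating one promoter never shifts another and
golden outputs stay stable.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; GFF3's 1-based closed
  convention is converted at the I/O boundary. The minus-strand TSS window
  is the coordinate mirror `[t - 200, t + 2000)`.
- "Distance between neighboring miRNAs" is the closest-end gap between
  loci, the conventional reading of locus distance; overlapping loci have
  negative gap and always chain.
- Promoter windows clipped at a chromosome boundary keep the intersecting
  part; only a window that clips to nothing is an error.
- Host ambiguity (several same-strand overlapping genes) resolves to the
  host with the strongest TSS support, tie-broken by gene id — fully
  deterministic in the input set.
- Mature-to-hairpin assignment requires both sequence containment
  (T/U-insensitive) and a shared name stem (species prefix, `mir`/`let`
  prefix and arm suffixes stripped; a trailing numeric paralog suffix on
  the hairpin is allowed). The stem rule is a heuristic stand-in for
  curated naming; matures with no assignment are discarded.
- When alignment blocks overlap on the reference, the first block in file
  order wins and a warning is logged.
- The common-element detector joins each element set with sentinel bytes
  and runs one vectorized match-length recurrence; every maximal common
  string equals a maximal diagonal match run, and a global substring filter
  enforces maximality. It is held to a brute-force substring-intersection
  oracle in the tests.
- Empirical p-values use the add-one estimator, never exactly zero. m
  counts only lengths actually observed; a `test_all_lengths` switch widens
  the family to every length up to the null's maximum for sensitivity
  analyses.
- One null is shared across all candidate genes of the same conservation
  stratum rather than rebuilt per gene; this is what makes a
  genome-scale scan feasible.
- Background pools exclude the query promoters themselves; pairing a
  promoter with itself is excluded when pools share members.
- Problem sizes in the test suite and the acceptance report: nulls of
  1,000-10,000 pairs over pools of 60-300 background promoters, 2,000
  query pairs for type-I calibration and 200 replicates for power; these
  sizes give Monte-Carlo error well below the margins being asserted.

## Known limitations

- The intergenic promoter window is a proxy; real pri-miRNA TSSs can lie
  far upstream of the pre-miRNA hairpin, and nothing here recovers them.
- Only the single selected TSS per gene is used; alternative promoters are
  out of scope.
- An intragenic miRNA and its host gene share a promoter outright, so the
  host is trivially "predicted" as a target of its own miRNA; downstream
  interpretation should treat host-gene hits accordingly.
- Sense-strand exact matching only: no reverse-complement matches, no
  mismatches or gaps in common-element detection.
- The resampling p-value is discrete; at small `n_pairs` its resolution is
  `1/(n_pairs + 1)`, which bounds the achievable significance.
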
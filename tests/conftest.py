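import numpy as np
import pytest

from comir import (
    FixtureSpec,
    PlantedMotif,
    make_genome,
)
from comir.simulate import make_alignments
from comir.workflow import determine_promoters, extract_elements

MOTIF_15 = "ACGTTGCATGCAAGT"


@pytest.fixture(scope="session")
def fixture_spec():
    """Small synthetic study: 12 genes, 2 intragenic + 3 intergenic miRNAs,
    one 15-nt motif shared between a miRNA promoter and one gene promoter."""
    return FixtureSpec(
        seed=11,
        n_genes=12,
        n_intragenic=2,
        n_intergenic=3,
        planted_motifs=(PlantedMotif(MOTIF_15, ("mir-ig1", "gene005")),),
    )


@pytest.fixture(scope="session")
def bundle(fixture_spec):
    return make_genome(fixture_spec)


@pytest.fixture(scope="session")
def promoter_set(bundle):
    return determine_promoters(
        bundle.genes,
        bundle.pre_mirnas,
        bundle.tss_records,
        bundle.override_intergenic,
        chrom_lengths={bundle.chrom: bundle.chrom_len},
    )


@pytest.fixture(scope="session")
def alignment_blocks(fixture_spec, promoter_set):
    return make_alignments(fixture_spec, promoter_set.all_promoters())


@pytest.fixture(scope="session")
def element_map(promoter_set, alignment_blocks):
    elements, counts = extract_elements(promoter_set.all_promoters(), alignment_blocks)
    return elements, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
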
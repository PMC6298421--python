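import pytest
from hypothesis import settings

from paralogon_scope.genome_io import GeneRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from paralogon_scope.synthetic_genome import DEFAULT_SPECIES_TREE, SimConfig, simulate
from paralogon_scope.wgd_timing import SpeciesTree

#: compact protein layout for fast simulator tests
SMALL_REGIONS = {
    "Nterm": (0, 10),
    "TM1": (10, 30),
    "IL3": (30, 60),
    "TM7": (60, 80),
    "Cterm": (80, 100),
}


def make_gene(
    gene_id="g1",
    species="gar",
    chrom="chr1",
    start=1000,
    strand="+",
    family_id="famA",
    exon_lens=(90,),
    intron_lens=(),
    protein=None,
):
    """Build a consistent GeneRecord from exon/intron lengths given in
    translation order (on '-' the first translated exon sits rightmost)."""
    genomic_exons = exon_lens if strand == "+" else exon_lens[::-1]
    genomic_introns = intron_lens if strand == "+" else intron_lens[::-1]
    placed = []
    pos = start
    for i, el in enumerate(genomic_exons):
        placed.append((pos, pos + el))
        pos += el
        if i < len(genomic_introns):
            pos += genomic_introns[i]
    end = pos
    cds = sum(exon_lens)
    if protein is None:
        protein = "A" * (cds // 3)
    exons = placed if strand == "+" else placed[::-1]
    return GeneRecord(
        gene_id=gene_id,
        species=species,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        family_id=family_id,
        exons=exons,
        protein=protein,
    )


@pytest.fixture(scope="session")
def species_tree():
    return SpeciesTree.from_newick(DEFAULT_SPECIES_TREE)


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulated dataset (4 families, 100-aa proteins)."""
    cfg = SimConfig(
        seed=42,
        families_per_chromosome=4,
        focal_family_index=1,
        regions=dict(SMALL_REGIONS),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Losses, translocations, local duplications and intron gains all off."""
    cfg = SimConfig(
        seed=7,
        families_per_chromosome=4,
        focal_family_index=1,
        regions=dict(SMALL_REGIONS),
        wgd_loss_prob=0.0,
        translocation_prob=0.0,
        local_dup_prob=0.0,
        intron_gain_rate=0.0,
    )
    return simulate(cfg)
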
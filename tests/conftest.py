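import numpy as np
import pytest

from heg_atlas import SyntheticConfig, run_cohort_analysis, simulate_phage_cohort
from heg_atlas.io import GeneRecord, PhageGenome

AA = "ACDEFGHIKLMNPQRSTVWY"

FLAGSHIP_CONFIG = dict(
    n_genomes=20, n_lineages=3, n_core=25, n_loci=4,
    mutation_rate=0.08, truncation_prob=0.15, seed=1,
)


@pytest.fixture(scope="session")
def flagship_cohort():
    """The cohort of the end-to-end recovery run: 20 genomes, 3 starter
    lineages, 25 core families, 4 insertion loci, 8% divergence per level,
    15% truncation."""
    return simulate_phage_cohort(SyntheticConfig(**FLAGSHIP_CONFIG))


@pytest.fixture(scope="session")
def flagship_analysis(flagship_cohort):
    genomes, _truth = flagship_cohort
    return run_cohort_analysis(genomes, k_phage_clusters=3, n_perm=1000, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A lighter cohort for per-module recovery tests."""
    cfg = SyntheticConfig(
        n_genomes=9, n_lineages=3, n_core=12, n_loci=3,
        mutation_rate=0.08, truncation_prob=0.2, seed=42,
    )
    return simulate_phage_cohort(cfg)


@pytest.fixture(scope="session")
def small_partition(small_cohort):
    """Ortholog partition of the small cohort (word-seed prescreen on)."""
    from heg_atlas import all_vs_all_similarity, mcl

    genomes, _ = small_cohort
    proteins = {g.gene_id: g.protein_seq for gm in genomes for g in gm.genes}
    edges = all_vs_all_similarity(proteins, prescreen=True)
    return mcl(edges, nodes=proteins.keys())


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutated(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(seq)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AA if a != seq[i]])
    return "".join(out)


def build_genome(genome_id: str, tags, strands=None, protein="MKTAYIAKQR") -> PhageGenome:
    """Tiny hand-built genome whose genes are placed 400 bp apart; only gene
    order, strand and identifiers matter to the callers."""
    strands = strands or ["+"] * len(tags)
    genes = []
    for i, (tag, strand) in enumerate(zip(tags, strands)):
        genes.append(
            GeneRecord(
                gene_id=f"{genome_id}|{tag}",
                genome_id=genome_id,
                start=100 + 400 * i,
                end=100 + 400 * i + 300,
                strand=strand,
                protein_seq=protein,
                product="",
            )
        )
    return PhageGenome(genome_id=genome_id, sequence="A" * (100 + 400 * len(tags) + 400), genes=genes)
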
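import pytest

from tnseq_essentials.genome import GeneAnnotation, GenomeSequence, index_ta_sites
from tnseq_essentials.simulate import SimulationConfig, assign_labels, simulate_genome, simulate_insertions


def make_ta_chromosome(length: int, ta_positions: list[int]) -> str:
    """All-G chromosome with TA dinucleotides planted at given T coordinates."""
    seq = ["G"] * length
    for p in sorted(ta_positions):
        seq[p - 1] = "T"
        seq[p] = "A"
    return "".join(seq)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests.

    200 genes on two 100-kb chromosomes, 4,000 insertions with the default
    biases (intergenic enrichment, essential-body suppression).
    """
    config = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chromosome_lengths=(100_000, 100_000),
        n_genes=200,
        n_insertions=4_000,
    )
    genome, genes = simulate_genome(config)
    ta_index = index_ta_sites(genome)
    labels = assign_labels(genes, config.fraction_essential, config.seed)
    library, truth = simulate_insertions(genome, genes, labels, config, ta_index=ta_index)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "ta_index": ta_index,
        "labels": labels,
        "library": library,
        "truth": truth,
    }
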
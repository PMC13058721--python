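"""Shared fixtures: a small simulated study reused across test modules."""

import pytest

from sixma.feature_annotation import build_partition
from sixma.synthetic_data import (
    SimulationConfig,
    plant_6mA,
    simulate_annotation,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_chrom=2, chrom_len_bp=200_000, n_genes=14)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome + annotation + partition + planted truth at desk scale."""
    genome = simulate_genome(small_config)
    genes, repeats = simulate_annotation(genome, small_config)
    partition = build_partition(genome, genes)
    truth = plant_6mA(
        genome, genes, repeats, small_config, n_sites=800, partition=partition
    )
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "repeats": repeats,
        "partition": partition,
        "truth": truth,
    }
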
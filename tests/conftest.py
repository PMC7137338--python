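import numpy as np
import pytest

from methcap.simdata import (
    GenomeModel,
    Chromosome,
    SimulationConfig,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        samples_per_group={"normal": 2, "primary": 2},
        chrom_lengths=(120_000,),
        n_genes=4,
        fragments_per_sample=5_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


def make_manual_genome(sequence: str, islands=None, genes=None, name="chr1"):
    """Hand-built single-chromosome genome for targeted tests."""
    return GenomeModel(
        chromosomes=[Chromosome(name, sequence)],
        islands={name: np.asarray(islands if islands is not None else []).reshape(-1, 2)},
        genes=list(genes or []),
    )
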
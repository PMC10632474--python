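import numpy as np
import pytest

from tradistat import SimConfig, simulate_genome, simulate_insertions


@pytest.fixture(scope="session")
def default_library():
    """The default study conditions: 2000 genes, 15% essential with zero leak,
    2% domain-essential with a 450-bp free block, one insertion per 11 bp."""
    cfg = SimConfig(seed=11)
    annotation, genome_length = simulate_genome(cfg)
    sites, truth = simulate_insertions(annotation, cfg, genome_length)
    return cfg, annotation, genome_length, sites, truth


@pytest.fixture(scope="session")
def leaky_library():
    """A library whose essential genes leak a few insertions, so the
    exponential component fits to a finite rate."""
    cfg = SimConfig(seed=7, n_genes=1200, essential_leak_density=0.002)
    annotation, genome_length = simulate_genome(cfg)
    sites, truth = simulate_insertions(annotation, cfg, genome_length)
    return cfg, annotation, genome_length, sites, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
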
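import pytest

from iescan import io, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """50 kb single-scaffold genome with 50 planted IESs."""
    cfg = simulate.SimConfig(seed=7, genome_length=50_000, n_scaffolds=1)
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_genome(small_dataset):
    return io.genome_dict(small_dataset.mac)
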
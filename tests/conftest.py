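import numpy as np
import pytest

from wgaqc.simulate import SimConfig, simulate_cohort


def tiny_config(seed: int = 3, **overrides) -> SimConfig:
    """A fast cohort exercising every stage: ~190 samples, 30 genes."""
    base = dict(
        seed=seed,
        n_genes=30,
        gene_length=800,
        intergenic=100,
        n_dna_samples=150,
        n_wga_samples=40,
        n_replicate_pairs={"DNA:DNA": 4, "WGA:DNA": 2, "WGA:WGA": 3},
        confounded_group_size=40,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_cohort(tiny_config())


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition cohort (~2000 samples x 200 genes)."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
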
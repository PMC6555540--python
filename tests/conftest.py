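import numpy as np
import pytest

from sgrmap import GimSimConfig, simulate_gim_cross, yeast_genome


@pytest.fixture(scope="session")
def genome():
    return yeast_genome()


@pytest.fixture(scope="session")
def noiseless_screen(genome):
    """One noiseless GIM screen with the suppressor mid-chromosome 16."""
    cfg = GimSimConfig(
        genome=genome,
        n_barcodes=4500,
        suppressor_locus=("chr16", 500_000),
        noise_cv=0.0,
        seed=11,
    )
    return cfg, simulate_gim_cross(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
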
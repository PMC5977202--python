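import numpy as np
import pytest

from hostcline.simulate import SimConfig, simulate_genotypes_reads, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimConfig.default(seed=7, n_snps=400, n_per_pop=20, depth_mean=5.0)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_survey(small_config, small_truth):
    return simulate_genotypes_reads(small_truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def certain_likelihoods(genotypes):
    """Hard genotypes -> degenerate likelihood rows."""
    g = np.asarray(genotypes, dtype=int)
    L = np.zeros(g.shape + (3,))
    np.put_along_axis(L, g[..., None], 1.0, axis=-1)
    return L
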
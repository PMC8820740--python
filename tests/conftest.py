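import numpy as np
import pandas as pd
import pytest

from ca1kit.simulate import SimConfig, gen_count_data, gen_gene_models


@pytest.fixture(scope="session")
def sim200():
    """Default-size simulated dataset shared across read-only tests."""
    cfg = SimConfig(n_genes=200, seed=7)
    models, genes, isoforms = gen_gene_models(cfg)
    data = gen_count_data(models, genes, isoforms, cfg)
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def nb_draws(rng, mean, dispersion, size):
    """Independent NB sampler used as a test-side oracle."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


@pytest.fixture(scope="session")
def two_group_meta():
    n = 4
    return pd.DataFrame({"group": ["A"] * n + ["B"] * n},
                        index=[f"s{i}" for i in range(2 * n)])
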
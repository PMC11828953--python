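import numpy as np
import pytest

from c4omics.simulate import SimConfig, gen_multiomics


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A quick five-species simulation used by several suites."""
    return SimConfig(seed=7, n_genes=400)


@pytest.fixture(scope="session")
def small_multiomics(small_cfg):
    return gen_multiomics(small_cfg)


@pytest.fixture(scope="session")
def noisefree_multiomics():
    cfg = SimConfig(seed=11, n_genes=300, noise_sd_rna=0.0,
                    noise_sd_protein=0.0, noise_sd_rpf=0.0)
    return cfg, gen_multiomics(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
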
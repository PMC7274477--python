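import pytest

import t3enh


@pytest.fixture(scope="session")
def default_config():
    return t3enh.SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return t3enh.generate_dataset(default_config)


@pytest.fixture(scope="session")
def default_report(default_config):
    return t3enh.run_all(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for fast structural tests."""
    return t3enh.SimConfig(seed=5, n_chrom=2, chrom_len=8_000_000,
                           n_regions=400, n_genes=300)
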
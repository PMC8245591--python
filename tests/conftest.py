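import numpy as np
import pytest

from holophage import synthetic


@pytest.fixture(scope="session")
def small_config():
    """A fast community: few, short contigs with dense links."""
    return synthetic.CommunityConfig(
        n_phages=6, n_hosts=4,
        phage_len_range=(5_000, 9_000),
        host_len_range=(12_000, 18_000),
        p_crispr_link=0.3, p_prophage_link=0.3, p_trna_link=0.3,
        prophage_len_range=(1_200, 2_500),
        stratified=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return synthetic.generate_community(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
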
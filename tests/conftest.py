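import numpy as np
import pytest

from wildsleep import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(n_individuals=5, n_nights=4, seed=11, coupling_prob=0.0)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sim.generate_group_truth(small_config)


@pytest.fixture(scope="session")
def small_frame(small_truth):
    return sim.render_minute_logvedba(small_truth)


@pytest.fixture(scope="session")
def tree_map():
    return sim.make_tree_map(6, (36.90, 0.29), seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20120801)
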
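import numpy as np
import pytest

from crossloco.network import NetworkConfig, init_model
from crossloco.synthetic import CohortSpec, cohort_to_speed_dataset, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_cfg():
    return NetworkConfig(input_len=40, n_filters=4, filter_width=3,
                         attn_hidden=4, head_hidden=4, dropout_rate=0.0)


@pytest.fixture
def tiny_model(tiny_net_cfg):
    return init_model(tiny_net_cfg, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick-to-generate cohort shared by read-only tests."""
    spec = CohortSpec(n_per_cell=4, series_len=150, seed=11)
    trajs, truth = generate_cohort(spec)
    return spec, trajs, truth


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    _, trajs, _ = small_cohort
    return cohort_to_speed_dataset(trajs)
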
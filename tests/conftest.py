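import numpy as np
import pytest

from connpred import SyntheticConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        P=16, n=40, k_true=4, M=4, noise_sd=0.05, score_noise_sd=0.5,
        n_predictive=2, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Desk-scale synthetic cohort shared across tests (P=16, p=120, n=40)."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SyntheticConfig(
        P=16, n=40, k_true=4, M=4, noise_sd=0.0, score_noise_sd=0.0,
        n_predictive=2, seed=11,
    )
    return generate_cohort(cfg)
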
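import numpy as np
import pytest

import connstab as cs


@pytest.fixture(scope="session")
def small_config():
    """A cheap 2-site cohort with a clear planted effect."""
    return cs.SyntheticConfig(
        n_sites=2,
        patients_per_site=5,
        controls_per_site=5,
        runs_per_subject=2,
        T=80,
        delta_r=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cs.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_link_fm(small_config, small_cohort):
    samples, runs = small_cohort
    return cs.extract_features(
        runs, samples, "ss_link_weight", block_dims=small_config.block_dims
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
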
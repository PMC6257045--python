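import numpy as np
import pytest

from thalparc import SyntheticConfig, build_basis, generate_cohort
from thalparc.clustering import ClusteringConfig


@pytest.fixture(scope="session")
def basis6():
    return build_basis(6)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_subjects=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fast_clustering():
    """Clustering profile for tests: fewer init restarts, same algorithm."""
    return ClusteringConfig(n_init_runs=50, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
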
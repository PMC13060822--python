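import numpy as np
import pytest

from actibrain.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small cohort: 12-node netmats (66 edges), 20 ROIs, n=600."""
    cfg = CohortConfig(n_participants=600, n_fc_nodes=12, n_gmv=20, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
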
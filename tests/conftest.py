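import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from twinpgs.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(n_families=400, n_loci=300, seed=123)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_pair_frame(x, y):
    """Long-format cohort frame from (n, 2) score and outcome arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    return pd.DataFrame({
        "family_id": np.repeat(np.arange(n), 2),
        "member": np.tile([1, 2], n),
        "gps": x.ravel(),
        "outcome": y.ravel(),
    })
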
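import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import etplineage as el

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 300-gene cohort with planted truth, shared across tests."""
    cfg = el.CohortSimConfig(n_genes=300, seed=11)
    expr, labels, truth = el.generate_cohort(cfg)
    return cfg, expr, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expr():
    """Hand-sized matrix for arithmetic checks."""
    return pd.DataFrame(
        {
            "S1": [1.0, 3.0, 5.0],
            "S2": [2.0, 4.0, 5.5],
            "S3": [3.0, 5.0, 6.0],
            "S4": [4.0, 6.0, 6.5],
        },
        index=["G1", "G2", "G3"],
    )
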
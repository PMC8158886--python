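import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metabometa.simulate import null_config
from metabometa import generate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_null_study():
    """Three small cohorts, 60 metabolites in 6 subclasses, no effects."""
    cfg = null_config(
        7, n_metabolites=60, n_subclasses=6, cohort_sizes=(60, 40, 30)
    )
    cohorts, set_db, truth = generate_study(cfg)
    return cfg, cohorts, set_db


@pytest.fixture()
def regression_fixture():
    """A 20-point deterministic (y, x, covariates) table with confounding."""
    rng = np.random.default_rng(42)
    n = 20
    confounder = rng.normal(size=n)
    x = 0.8 * confounder + rng.normal(size=n)
    y = -5.0 * x + 3.0 * confounder + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "c": confounder})
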
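import numpy as np
import pandas as pd
import pytest

from costlines import (ErrorSpec, GeneratorConfig, gamma_world,
                       generate_cohort, heavy_tail_world, lognormal_world)


@pytest.fixture(scope="session")
def gamma_cohort():
    """Mid-size cohort from the correctly specified gamma world."""
    return generate_cohort(gamma_world(seed=11), 20_000)


@pytest.fixture(scope="session")
def heavy_cohort():
    """Heavy-tailed heteroscedastic cohort (log-t3 errors)."""
    return generate_cohort(heavy_tail_world(seed=12), 20_000)


@pytest.fixture(scope="session")
def lognormal_cohort():
    """Homoscedastic lognormal cohort."""
    return generate_cohort(lognormal_world(seed=13), 20_000)


@pytest.fixture()
def tiny_config():
    """Two-category, one-line config for fast deterministic checks."""
    return GeneratorConfig(
        category_probs={"1-0": 0.6, "5-1": 0.4},
        use_prob={"pharmacy": 0.5},
        base_cost={"pharmacy": 100.0},
        effect={"1-0": 1.0, "5-1": 10.0},
        sex_effect=0.9,
        age_slope=1.01,
        error_family={"pharmacy": ErrorSpec("lognormal", sigma=0.5)},
        seed=7,
    ).validate()


@pytest.fixture()
def small_cohort():
    """Hand-built 10-row cohort: 4 positive pharmacy costs."""
    return pd.DataFrame({
        "person_id": np.arange(10),
        "sex": ["female", "male"] * 5,
        "age": np.linspace(20, 80, 10),
        "acrg3": ["1-0", "1-0", "5-1", "5-1", "1-0",
                  "5-1", "1-0", "5-1", "1-0", "1-0"],
        "cost_pharmacy": [0.0, 10.0, 0.0, 250.0, 0.0,
                          120.0, 0.0, 0.0, 30.0, 0.0],
    })
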
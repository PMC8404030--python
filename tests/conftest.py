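import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ampindex as ai

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_panel() -> ai.IndicatorPanel:
    """4 units x 3 indicators with known values on heterogeneous scales."""
    return ai.IndicatorPanel(
        pd.DataFrame(
            {
                "life_exp": [80.0, 82.0, 78.0, 84.0],
                "mortality": [5.0, 3.0, 9.0, 1.0],
                "spending": [1000.0, 1500.0, 800.0, 2000.0],
            },
            index=["north", "centre", "south", "islands"],
        )
    )


@pytest.fixture
def table5() -> pd.DataFrame:
    return ai.load_fixture("table5_quality")


@pytest.fixture
def published() -> pd.DataFrame:
    return ai.published_scores()


def random_panel(rng: np.random.Generator, n: int, m: int) -> ai.IndicatorPanel:
    """A random panel with distinct column min/max."""
    vals = rng.normal(0, 1, (n, m)) * rng.uniform(0.5, 50, m) + rng.uniform(
        -100, 100, m
    )
    # ensure every column has a strict spread
    vals[0] += 1.0
    return ai.IndicatorPanel(
        pd.DataFrame(
            vals,
            index=[f"u{i}" for i in range(n)],
            columns=[f"x{j}" for j in range(m)],
        )
    )
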
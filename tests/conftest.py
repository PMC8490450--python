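import logging

import numpy as np
import pandas as pd
import pytest

from hepatotype.io import ExpressionMatrix
from hepatotype.simulate import SimulationConfig, simulate_expression

logging.getLogger("hepatotype").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic expression cohort (4 tumor classes, n=40 each)."""
    cfg = SimulationConfig(seed=11)
    expr, centroids, truth = simulate_expression(cfg, seed=11)
    return cfg, expr, centroids, truth


@pytest.fixture
def small_expr():
    """A tiny deterministic 5-gene x 4-sample matrix."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0, 8, (5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(values=values)
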
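import numpy as np
import pandas as pd
import pytest

from luadstrat import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=120, n_background_genes=200, seed=11)
    )


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(5, 1, size=(6, 4)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(4)],
    )
    return ExpressionMatrix(data)
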
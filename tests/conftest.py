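import numpy as np
import pandas as pd
import pytest

from m6apattern import (
    ClinicalTable,
    CohortSimulationParams,
    ExpressionMatrix,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One planted 3-pattern cohort shared by read-only tests."""
    return generate_cohort(CohortSimulationParams(seed=11))


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(8, 1, size=(20, 12)),
        index=[f"G{i:02d}" for i in range(20)],
        columns=[f"S{i:02d}" for i in range(12)],
    )
    return ExpressionMatrix(data, scale="log2")


@pytest.fixture()
def simple_clinical():
    rng = np.random.default_rng(1)
    n = 40
    time = rng.exponential(30, size=n)
    event = (rng.random(n) < 0.7).astype(int)
    return ClinicalTable(
        pd.DataFrame(
            {"time": time, "event": event}, index=[f"S{i:03d}" for i in range(n)]
        )
    )
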
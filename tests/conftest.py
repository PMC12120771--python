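import numpy as np
import pandas as pd
import pytest

from tflens import (
    ExpressionMatrix,
    simulate_cohort,
    simulate_time_series,
)


@pytest.fixture(scope="session")
def cohort_default():
    """Default simulated two-lineage cohort (matrix, labels, truth)."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def series_default():
    """Default simulated four-timepoint series (matrices, truth)."""
    return simulate_time_series(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def small_matrix():
    """3-gene x 2-sample toy matrix."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]],
            index=["AR", "ASCL1", "FOXA1"],
            columns=["s1", "s2"],
        )
    )


def random_matrix(rng, n_genes=50, n_samples=8) -> ExpressionMatrix:
    values = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:03d}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
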
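import numpy as np
import pandas as pd
import pytest

from matrisig import Centroid, CohortSimSpec, ExpressionMatrix, simulate_cohort
from matrisig.expression import CASE, CONTROL


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """5 features, 3+3 samples, linear intensities."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(mean=6, sigma=0.4, size=(5, 6)),
        index=[f"f{i}" for i in range(5)],
        columns=["c1", "c2", "c3", "v1", "v2", "v3"],
    )
    condition = {"c1": CASE, "c2": CASE, "c3": CASE,
                 "v1": CONTROL, "v2": CONTROL, "v3": CONTROL}
    return ExpressionMatrix(values, scale="linear", condition=condition)


@pytest.fixture
def small_centroid() -> Centroid:
    weights = pd.Series(
        [3.74, 3.1, 2.39, -3.31, -1.63, 2.0, 1.8, -2.2],
        index=["GPC1", "VCAN", "TNC", "WISP2", "GAS6", "POSTN", "TIMP1", "SFRP1"],
    )
    return Centroid(weights)


@pytest.fixture
def planted_cohort(small_centroid):
    """Simulated cohort with a latent high-risk state (seed fixed)."""
    spec = CohortSimSpec(
        n_patients=400,
        centroid=small_centroid,
        frac_centroid_like=0.4,
        hr_true=2.5,
        seed=11,
    )
    return simulate_cohort(spec)
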
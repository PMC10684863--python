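import numpy as np
import pandas as pd
import pytest

from immunorhythm import (CohortTable, generate_cohort, null_params,
                          study_params)
from immunorhythm.panel import LINEAGES, PHENOTYPES


def make_cohort_frame(n: int = 24, seed: int = 0,
                      ages=None, sexes=None) -> pd.DataFrame:
    """Small hand-rolled cohort frame with valid compositions."""
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = rng.integers(9, 228, n)
    if sexes is None:
        sexes = np.where(np.arange(n) % 2 == 0, "male", "female")
    data = {"subject_id": [f"T{i:03d}" for i in range(n)],
            "sex": sexes, "age_months": ages}
    for members in LINEAGES.values():
        raw = rng.dirichlet(np.ones(4), size=n) * 100.0
        for k, p in enumerate(members):
            data[p] = raw[:, k]
    return pd.DataFrame(data)


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(make_cohort_frame(n=48, seed=3))


@pytest.fixture(scope="session")
def study_cohort() -> CohortTable:
    """One study synthetic cohort (published group sizes, seed 0)."""
    return generate_cohort(study_params(), seed=0)


@pytest.fixture(scope="session")
def null_cohort() -> CohortTable:
    """Null cohort: no trends, no sex effects, identity latent correlation."""
    return generate_cohort(null_params(), seed=0)
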
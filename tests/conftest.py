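import numpy as np
import pandas as pd
import pytest

import hemiasym as ha


@pytest.fixture(scope="session")
def small_cohort() -> ha.Cohort:
    """A 40-subject toy cohort with default planted structure."""
    return ha.generate_cohort(ha.CohortConfig(n_subjects=40, n_vertices=36, seed=11))


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    """Amplitude and asymmetry network-epoch matrices of the toy cohort."""
    c = small_cohort
    nem_a = ha.aggregate_cohort_arrays(
        c.amplitude(), c.partition, c.subject_ids, c.epochs, "amplitude"
    )
    nem_d = ha.aggregate_cohort_arrays(
        c.asymmetry(), c.partition, c.subject_ids, c.epochs, "asymmetry"
    )
    return nem_a, nem_d


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_subject_table(n: int, seed: int = 0) -> pd.DataFrame:
    """A covariate table without brain maps, for split/adjustment tests."""
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            "age": r.normal(28.8, 3.7, n),
            "sex": np.where(r.random(n) < 0.6, "F", "M"),
            "race": r.choice(["white", "black", "asian", "other"], n),
            "bmi": r.normal(26, 4, n),
        }
    )
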
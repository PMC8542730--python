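import numpy as np
import pandas as pd
import pytest

import hfphenomap as hp
from hfphenomap import prep


def toy_patient_table(n=10, seed=0):
    """Small raw patient table exercising every exclusion path."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "trial_id": ["T1"] * (n // 2) + ["T2"] * (n - n // 2),
            "arm": np.where(rng.random(n) < 0.5, "bb", "placebo"),
            "rhythm": ["SR"] * n,
            "age": rng.normal(64, 10, n),
            "gender": np.where(rng.random(n) < 0.25, "female", "male"),
            "bmi": rng.normal(27, 4, n),
            "heart_rate": rng.normal(80, 10, n),
            "sbp": rng.normal(124, 15, n),
            "lvef": rng.uniform(15, 45, n),
            "prior_mi": rng.integers(0, 2, n),
            "nyha": rng.integers(1, 5, n),
            "creatinine": rng.normal(105, 20, n),
            "acei_arb": rng.integers(0, 2, n),
            "diuretic": rng.integers(0, 2, n),
            "anticoagulant": rng.integers(0, 2, n),
            "digoxin": rng.integers(0, 2, n),
            "death": rng.integers(0, 2, n),
            "followup_years": rng.exponential(1.8, n),
        }
    )
    df.index.name = "patient_id"
    return df


@pytest.fixture
def toy_table():
    return toy_patient_table()


@pytest.fixture(scope="session")
def structured_cohort():
    """Strongly separated planted cohort (~4000 patients), shared across
    recovery tests."""
    spec = hp.default_cohort_spec(seed=5, separation=3.5,
                                  n_scale=4000 / 15659)
    return hp.generate_cohort(spec), spec


@pytest.fixture(scope="session")
def structured_sr(structured_cohort):
    """Prepared SR stratum of the structured cohort + its hidden truth."""
    table, spec = structured_cohort
    sub, X, report = prep.prepare_stratum(table, "SR")
    truth = table.loc[sub.index, "true_cluster"].to_numpy()
    return sub, X, truth
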
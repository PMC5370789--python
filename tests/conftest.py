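import numpy as np
import pandas as pd
import pytest

from obmatch.cohort import COHORT_COLUMNS, COMORBIDITY_COLUMNS, CohortTable, compute_cci


def make_cohort(rows, censor_default=1000):
    """Build a small cohort frame from partial row dicts.

    Unspecified covariates default to a 50-year-old male HD/NHI patient
    with no comorbidity; cci is recomputed from flags and age.
    """
    recs = []
    for i, row in enumerate(rows):
        r = {
            "id": i + 1, "age": 50, "sex": "M", "modality": "HD",
            "insurance": "NHI",
            **{c: 0 for c in COMORBIDITY_COLUMNS},
            "tx_time": np.nan, "death_time": np.nan, "mace_time": np.nan,
            "censor_time": censor_default,
        }
        r.update(row)
        r["cci"] = compute_cci({c: r[c] for c in COMORBIDITY_COLUMNS}, r["age"])
        recs.append(r)
    df = pd.DataFrame(recs)[COHORT_COLUMNS]
    return CohortTable(df, meta={"source": "fixture"})


class FixedScores:
    """Stand-in propensity model assigning preset scores by subject id."""

    def __init__(self, scores: dict):
        self.scores = scores

    def score_samples(self, df):
        return np.array([self.scores[i] for i in df["id"]], float)


@pytest.fixture
def three_subject_cohort():
    """A transplanted at day 100, B at day 200, C never; all followed 400 days."""
    return make_cohort([
        {"id": 1, "tx_time": 100, "censor_time": 400},
        {"id": 2, "tx_time": 200, "censor_time": 400},
        {"id": 3, "censor_time": 400},
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One filtered cohort from the default confounded scenario (n=2000)."""
    from obmatch import SimulationConfig, apply_min_survival_filter, simulate_cohort
    return apply_min_survival_filter(simulate_cohort(SimulationConfig(n=2000, seed=11)))
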
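import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from riskscreen import accuracy as acc
from riskscreen.synth_cohort import make_table2_fixture

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def fixture_confusion(horizon: int) -> pd.DataFrame:
    """Confusion-by-cutoff table rebuilt from the printed per-score counts."""
    return acc.confusion_from_fixture(make_table2_fixture(horizon), horizon=horizon)


@pytest.fixture(scope="session")
def confusion_1y():
    return fixture_confusion(1)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny hand-built schema frame: 3 subjects, one of each censor cause."""
    return pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "male": [1, 0, 1],
            "prior_conviction": [0, 1, 0],
            "age_at_assessment": [24.0, 40.0, 31.5],
            "alcohol": [0, 0, 1],
            "drug": [1, 0, 0],
            "low_education": [0, 1, 0],
            "father_violent": [0, 0, 0],
            "mother_violent": [0, 0, 0],
            "father_alcohol": [0, 0, 1],
            "mother_alcohol": [0, 0, 0],
            "followup_years": [0.4, 12.0, 3.25],
            "event": [1, 0, 0],
            "censor_cause": ["event", "end_of_study", "death_or_emigration"],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
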
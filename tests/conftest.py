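import numpy as np
import pandas as pd
import pytest

from motortrace.metrics import compute_metric_table
from motortrace.paths import PathConfig
from motortrace.subjects import simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Shortened task layout for fast unit tests (2 trials of ~10 s)."""
    return PathConfig(n_segments=8, n_trials=2, trial_duration=10.0)


@pytest.fixture(scope="session")
def cohort_table():
    """Small mixed cohort metric table shared by classification tests."""
    cfg = PathConfig(n_trials=3)
    sessions = simulate_cohort({"control": 4, "pd": 2, "et": 2}, cfg=cfg, seed=101)
    return pd.concat([compute_metric_table(s) for s in sessions], ignore_index=True)


@pytest.fixture(scope="session")
def control_table(cohort_table):
    return cohort_table[cohort_table["group"] == "control"]
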
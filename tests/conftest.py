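import numpy as np
import pandas as pd
import pytest

from valsearch.cohort import (
    young_hyper, sample_population, simulate_learning_agent,
    simulate_search_participant,
)
from valsearch.design import build_learning_schedule, build_search_schedule


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants from the young-group preset with their trial data."""
    parts = sample_population(young_hyper(), 6, 123)
    learning, search = [], []
    for i, p in enumerate(parts):
        learning.append(simulate_learning_agent(
            p, build_learning_schedule(500 + i), seed=900 + i))
        search.append(simulate_search_participant(
            p, build_search_schedule(700 + i), seed=800 + i, dt=5e-4))
    return {
        "participants": parts,
        "learning": pd.concat(learning, ignore_index=True),
        "search": pd.concat(search, ignore_index=True),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
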
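import numpy as np
import pandas as pd
import pytest

from mjm.data import TrialDataset
from mjm.simulate import ScenarioConfig, TrueParams, generate_dataset


@pytest.fixture
def tiny_tables():
    """Three-subject fixture: 2 groups, 7 measurements, 3 survival rows.

    Subject A has an event at 3.2, B is censored at 12.25, C has an event
    at 0.4 (only the baseline measurement precedes it).
    """
    longitudinal = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B", "B", "B", "C"],
            "group_id": ["g1", "g1", "g1", "g2", "g2", "g2", "g1"],
            "time": [0.0, 0.5, 3.0, 0.0, 0.5, 4.5, 0.0],
            "y": [15.2, 14.0, 11.8, 18.1, 17.5, 12.0, 16.6],
        }
    )
    survival = pd.DataFrame(
        {
            "subject_id": ["A", "B", "C"],
            "group_id": ["g1", "g2", "g1"],
            "observed_time": [3.2, 12.25, 0.4],
            "event": [1, 0, 1],
        }
    )
    groups = pd.DataFrame({"group_id": ["g1", "g2"], "treatment": [1, 0]})
    return longitudinal, survival, groups


@pytest.fixture
def tiny_dataset(tiny_tables):
    return TrialDataset(*tiny_tables)


@pytest.fixture(scope="session")
def small_scenario():
    """Small but fully structured simulated scenario (fast to generate).

    The Weibull scale is fixed explicitly so no calibration runs in unit
    tests; the implied censoring is moderate.
    """
    return ScenarioConfig(
        L=8,
        group_size=12,
        Q=3,
        var_v=5.0,
        var_g=0.4,
        truths=TrueParams(scale=1.6786, var_v=5.0, var_g=0.4),
        seed=20260901,
    )


@pytest.fixture(scope="session")
def small_sim(small_scenario):
    return generate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_sim_dataset(small_sim):
    return small_sim[0]
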
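import numpy as np
import pandas as pd
import pytest

from sleepjitai import synthetic_cohort as sc
from sleepjitai.sleep_scoring import ActivityEpochSeries


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-participant observational cohort with epoch counts and EMA."""
    cfg = sc.CohortConfig(n_participants=16, group_b_fraction=0.5)
    return sc.generate_study1_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def trial_data():
    """A default (group-B-responsive) microrandomized trial."""
    return sc.generate_study2_trial(sc.TrialConfig(), seed=21)


def make_series(counts, worn=None, start="2022-02-01 12:00:00", pid="p1"):
    counts = np.asarray(counts)
    if worn is None:
        worn = np.ones(len(counts), dtype=bool)
    return ActivityEpochSeries(
        participant_id=pid, start_time=pd.Timestamp(start), counts=counts, worn=worn
    )
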
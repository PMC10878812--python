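"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from dyadsync.fnirs import default_montage, first_level
from dyadsync.synthetic import (BehaviourParams, generate_behaviour,
                                generate_task_schedule,
                                simulate_fnirs_cohort)


@pytest.fixture(scope="session")
def schedule20():
    return generate_task_schedule(11, n_blocks=20)


@pytest.fixture(scope="session")
def schedule40():
    return generate_task_schedule(12, n_blocks=40)


@pytest.fixture(scope="session")
def trials_small(schedule20):
    """Default-calibration trial table, 8 participants per group."""
    return generate_behaviour(BehaviourParams(n_per_group=8, seed=21),
                              schedule20)


@pytest.fixture(scope="session")
def roi_estimates_small(schedule20):
    """First-level ROI estimates for a small simulated cohort."""
    mont = default_montage(long_per_roi=1, n_short=2)
    sched = generate_task_schedule(13, n_blocks=8)
    rows = []
    for pid, group, raw, _ in simulate_fnirs_cohort(5, sched, mont, seed=31):
        _, roi = first_level(raw)
        roi["participant_id"] = pid
        roi["group"] = group
        rows.append(roi)
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
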
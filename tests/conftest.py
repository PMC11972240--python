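"""Shared fixtures: hand-built trials and a reusable simulated cohort."""

import numpy as np
import pandas as pd
import pytest

import foragekit as fk


def make_trial(
    coords,
    times=None,
    trial_id="t1",
    participant_id="p1",
    condition="static",
    age_group="adult",
    leave_time=None,
):
    """Build a trial of target picks from coordinates (and optional times)."""
    if times is None:
        times = [0.5 * (i + 1) for i in range(len(coords))]
    events = [
        fk.PickEvent(index=i + 1, t=float(t), x=float(x), y=float(y),
                     kind="target", points=2)
        for i, ((x, y), t) in enumerate(zip(coords, times))
    ]
    if leave_time is None and events:
        leave_time = events[-1].t + 0.3
    return fk.Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=condition,
        age_group=age_group,
        set_size=40,
        events=events,
        leave_time=leave_time,
    )


@pytest.fixture
def square_trial():
    return make_trial([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture(scope="session")
def mvt_cohort():
    """30 strict-MVT agents foraging 40 static depleting patches each."""
    arena = fk.ArenaConfig(set_size=40, speed=0.0)
    agent = fk.AgentConfig(rule=fk.LeavingRule("mvt", 1.0))
    return fk.simulate_cohort(arena, agent, 30, 40, seed=20240901,
                              condition="static")


@pytest.fixture(scope="session")
def mvt_decisions(mvt_cohort):
    return fk.build_decision_table(mvt_cohort.trials)
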
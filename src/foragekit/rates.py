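"""Marginal-Value-Theorem intake rates and the RIAIR.

The Marginal Value Theorem (MVT) says an optimal forager should leave a
patch when the instantaneous intake rate drops to the average intake rate.
The RIAIR — Ratio of Instantaneous to Average Intake Rate — expresses this
as a dimensionless quantity: staying is MVT-optimal while RIAIR > 1, and
the optimal moment to leave is when it reaches 1.  RIAIR values sustained
below 1 at observed leaving points indicate overharvesting.

Per collected target i (times relative to trial onset, t_0 = 0):

* instantaneous rate = v_i / (t_i − t_{i−1})
* average rate       = (Σ_{j≤i} v_j) / (t_i + travel_offset)
* RIAIR              = instantaneous / average

with v_i = 1 in ``items`` mode (the MVT formulation on intake counts) or
the pick's score delta in ``points`` mode.  The travel offset defaults to
0: the average rate is computed within the trial only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TRAVEL_COST_S, Trial


@dataclass(frozen=True)
class RateRecord:
    """Intake rates at the n-th collected target."""

    n: int
    t: float
    instantaneous_rate: float
    average_rate: float
    riair: float


def riair_series(
    trial: Trial,
    value_mode: str = "items",
    include_travel: bool = False,
) -> list[RateRecord]:
    """RIAIR record per collected target, aligned to the pick ordinal n.

    ``value_mode="items"`` values every target at 1, so the series depends
    only on pick times; ``"points"`` uses each pick's score delta and adds
    distractor penalties to the cumulative value (sensitivity analysis).
    ``include_travel`` adds the fixed 2-s travel cost to the denominator
    of the average rate.
    """
    if value_mode not in ("items", "points"):
        raise ValueError(f"unknown value_mode {value_mode!r}")
    targets = trial.targets
    if not targets:
        return []
    times = np.array([e.t for e in targets], dtype=float)
    if np.any(np.diff(np.concatenate([[0.0], times])) <= 0):
        raise ValueError(
            f"trial {trial.trial_id!r}: pick times must be strictly increasing"
        )
    travel = TRAVEL_COST_S if include_travel else 0.0

    if value_mode == "items":
        values = np.ones(len(targets))
        cum = np.cumsum(values)
    else:
        values = np.array([float(e.points) for e in targets])
        # cumulative value includes distractor penalties incurred so far
        all_events = sorted(trial.events, key=lambda e: e.t)
        cum = np.array(
            [
                sum(ev.points for ev in all_events if ev.t <= t)
                for t in times
            ],
            dtype=float,
        )

    prev = np.concatenate([[0.0], times[:-1]])
    inst = values / (times - prev)
    avg = cum / (times + travel)
    riair = inst / avg
    return [
        RateRecord(
            n=i + 1,
            t=float(times[i]),
            instantaneous_rate=float(inst[i]),
            average_rate=float(avg[i]),
            riair=float(riair[i]),
        )
        for i in range(len(targets))
    ]
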
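"""Foraging event-log data model and CSV I/O.

A *trial* (also called a patch or display) is one search screen: the
observer taps targets, each tap is logged with a trial-relative timestamp
and the screen coordinates of the item at the instant it was collected,
and at some point the observer abandons the display ("leaves the patch"),
paying a fixed travel cost before the next one.

The event-log CSV dialect is one row per event with columns::

    session_id, participant_id, age_group, condition, trial_id, set_size,
    event_index, event_type {target|distractor|leave}, t_sec, x_px, y_px,
    points

Coordinates are screen pixels, origin top-left, y increasing downward.
Timestamps are seconds since trial onset; the 2-s travel cost between
patches is session metadata, never part of a trial's clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

EVENT_COLUMNS = [
    "session_id",
    "participant_id",
    "age_group",
    "condition",
    "trial_id",
    "set_size",
    "event_index",
    "event_type",
    "t_sec",
    "x_px",
    "y_px",
    "points",
]

#: Default scoring: a collected target is worth +2, a tapped distractor −1.
TARGET_POINTS = 2
DISTRACTOR_POINTS = -1

#: Fixed inter-patch travel delay, seconds (session metadata).
TRAVEL_COST_S = 2.0

#: Organization indicators need at least three collected targets.
MIN_PICKS = 3


class EventLogFormatError(ValueError):
    """The event-log file violates the documented CSV dialect."""


class EventLogValidationError(ValueError):
    """The event log parses but violates a trial-level invariant."""


@dataclass(frozen=True)
class PickEvent:
    """One item selection within a trial.

    Parameters
    ----------
    index : int
        1-based ordinal position within the trial.
    t : float
        Seconds since trial onset; strictly increasing within a trial.
    x, y : float
        Screen coordinates (pixels) of the item at the collection instant.
    kind : str
        ``"target"`` or ``"distractor"``.
    points : int
        Signed score delta (+2 target / −1 distractor by default).
    """

    index: int
    t: float
    x: float
    y: float
    kind: str
    points: int

    def __post_init__(self) -> None:
        if self.kind not in ("target", "distractor"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise ValueError("event time must be non-negative")


@dataclass
class Trial:
    """One patch visit: ordered pick events plus the leave event."""

    trial_id: str
    participant_id: str
    condition: str
    age_group: str
    set_size: int
    events: list[PickEvent] = field(default_factory=list)
    leave_time: float | None = None
    depleted: bool = False
    session_id: str = ""

    def __post_init__(self) -> None:
        ts = [e.t for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise EventLogValidationError(
                f"trial {self.trial_id!r}: event times not strictly increasing"
            )
        if self.leave_time is not None and ts and self.leave_time < ts[-1]:
            raise EventLogValidationError(
                f"trial {self.trial_id!r}: leave_time precedes last event"
            )

    @property
    def targets(self) -> list[PickEvent]:
        """Collected-target events only; distractor taps are excluded
        from the decision series and from organization coordinates."""
        return [e for e in self.events if e.kind == "target"]

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target_coords(self) -> list[tuple[float, float]]:
        return [(e.x, e.y) for e in self.targets]

    def target_times(self) -> list[float]:
        return [e.t for e in self.targets]


@dataclass
class DecisionRecord:
    """One stay/leave decision, made at the n-th collected target.

    Every target pick from the ``min_picks``-th onward is a decision: the
    last pick before leaving is a *leave* decision, all earlier ones are
    *stay* decisions.  Indicator fields are filled in by the pipeline.
    """

    trial_id: str
    participant_id: str
    condition: str
    age_group: str
    n: int
    label: str  # "stay" | "leave"
    t: float
    best_r: float | None = None
    mean_itd: float | None = None
    pao: float | None = None
    intersection_rate: float | None = None
    riair: float | None = None
    z_best_r: float | None = None
    z_mean_itd: float | None = None
    z_pao: float | None = None
    z_intersection_rate: float | None = None
    composite_weighted: float | None = None
    composite_unweighted: float | None = None
    depleted: bool = False


def extract_decisions(trial: Trial, min_picks: int = MIN_PICKS) -> list[DecisionRecord]:
    """Convert a trial into labeled stay/leave decision records.

    Returns one record per collected target from the ``min_picks``-th
    onward — ``max(0, N − min_picks + 1)`` records for N collected
    targets — with only the final one labeled ``leave``.  Trials with
    fewer than ``min_picks`` targets yield an empty list.
    """
    if min_picks < MIN_PICKS:
        raise ValueError(
            f"min_picks must be >= {MIN_PICKS}: organization indicators are "
            "undefined on fewer than three collection points"
        )
    targets = trial.targets
    n_total = len(targets)
    records = []
    for n in range(min_picks, n_total + 1):
        ev = targets[n - 1]
        records.append(
            DecisionRecord(
                trial_id=trial.trial_id,
                participant_id=trial.participant_id,
                condition=trial.condition,
                age_group=trial.age_group,
                n=n,
                label="leave" if n == n_total else "stay",
                t=ev.t,
                depleted=trial.depleted,
            )
        )
    return records


def _trial_from_rows(key: tuple, rows: pd.DataFrame) -> Trial:
    participant_id, condition, trial_id = key
    rows = rows.sort_values("t_sec", kind="stable")
    picks = rows[rows["event_type"].isin(["target", "distractor"])]
    ts = picks["t_sec"].to_numpy()
    if len(ts) != len(set(ts)):
        raise EventLogValidationError(
            f"trial {trial_id!r}: duplicate event timestamps"
        )
    events = [
        PickEvent(
            index=i + 1,
            t=float(r.t_sec),
            x=float(r.x_px),
            y=float(r.y_px),
            kind=str(r.event_type),
            points=int(r.points),
        )
        for i, r in enumerate(picks.itertuples())
    ]
    leave_rows = rows[rows["event_type"] == "leave"]
    leave_time = float(leave_rows["t_sec"].iloc[0]) if len(leave_rows) else None
    first = rows.iloc[0]
    return Trial(
        trial_id=str(trial_id),
        participant_id=str(participant_id),
        condition=str(condition),
        age_group=str(first["age_group"]),
        set_size=int(first["set_size"]),
        events=events,
        leave_time=leave_time,
        session_id=str(first["session_id"]),
    )


def read_event_log(path: str | Path) -> list[Trial]:
    """Read an event-log CSV into validated :class:`Trial` objects.

    Trials are grouped by (participant, condition, trial_id) and events
    sorted by time; the read is therefore invariant to row order.  A
    missing mandatory column raises :class:`EventLogFormatError`;
    non-monotone or duplicate timestamps within a trial raise
    :class:`EventLogValidationError` naming the trial.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogFormatError(f"{path}: missing mandatory columns {missing}")
    bad_kind = ~df["event_type"].isin(["target", "distractor", "leave"])
    if bad_kind.any():
        lines = (df.index[bad_kind] + 2).tolist()  # +2: header + 1-based
        raise EventLogFormatError(
            f"{path}: unknown event_type at line(s) {lines[:10]}"
        )
    trials = []
    for key, rows in df.groupby(
        ["participant_id", "condition", "trial_id"], sort=True
    ):
        trials.append(_trial_from_rows(key, rows))
    return trials


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Flatten trials back into the event-log row format."""
    rows = []
    for tr in trials:
        for ev in tr.events:
            rows.append(
                {
                    "session_id": tr.session_id,
                    "participant_id": tr.participant_id,
                    "age_group": tr.age_group,
                    "condition": tr.condition,
                    "trial_id": tr.trial_id,
                    "set_size": tr.set_size,
                    "event_index": ev.index,
                    "event_type": ev.kind,
                    "t_sec": ev.t,
                    "x_px": ev.x,
                    "y_px": ev.y,
                    "points": ev.points,
                }
            )
        if tr.leave_time is not None:
            rows.append(
                {
                    "session_id": tr.session_id,
                    "participant_id": tr.participant_id,
                    "age_group": tr.age_group,
                    "condition": tr.condition,
                    "trial_id": tr.trial_id,
                    "set_size": tr.set_size,
                    "event_index": len(tr.events) + 1,
                    "event_type": "leave",
                    "t_sec": tr.leave_time,
                    "x_px": float("nan"),
                    "y_px": float("nan"),
                    "points": 0,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_event_log(trials: Iterable[Trial], path: str | Path) -> None:
    """Write trials to the event-log CSV dialect (round-trips with
    :func:`read_event_log` on all mandatory fields)."""
    trials_to_frame(trials).to_csv(path, index=False)
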
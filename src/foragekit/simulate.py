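"""Synthetic visual-foraging event logs with known ground truth.

The simulator emulates touchscreen foraging displays: 40–180 items of
which 20–30% are targets, static or drifting at a constant speed (44 or
88 px/s) with direction redrawn at semi-random intervals and reflection
at the display edges.  A simulated agent collects targets one by one —
nearest-first, in noisy reading order, or at random — with a pick-time
model (base latency plus movement time, multiplicative lognormal noise)
that makes instantaneous intake rates decline as the patch depletes.  A
parameterized quitting rule ends the trial:

* ``mvt(θ)`` — leave at the first pick (≥ min_picks) whose RIAIR < θ;
  θ = 1 is the strict Marginal-Value-Theorem forager.
* ``giving_up_time(G)`` — leave when the anticipated time to the next
  target exceeds G seconds.
* ``fixed_count(k)`` — leave after k targets.
* ``random(p)`` — leave with probability p after each pick.

Every trial is reproducible from its seed, and the per-pick rule
evaluations are returned as ground truth so recovery tests can check the
analysis pipeline against the generating rule.  The simulator provides
statistical structure for testing the pipeline; it makes no claim to
model human reaction times, memory load, or development.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    DISTRACTOR_POINTS,
    TARGET_POINTS,
    TRAVEL_COST_S,
    PickEvent,
    Trial,
)


@dataclass(frozen=True)
class ArenaConfig:
    """Display geometry and item dynamics (defaults match a 1400×1500-px
    touchscreen with 20–30% targets)."""

    width: float = 1400.0
    height: float = 1500.0
    set_size: int = 40
    target_proportion: float | None = None  # None: drawn U(0.20, 0.30)
    speed: float = 0.0  # px/s; 0 static, 44 slow, 88 fast
    direction_change_bounds: tuple[float, float] = (0.5, 2.0)  # s

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.target_proportion is not None and not (
            0.0 < self.target_proportion <= 1.0
        ):
            raise ValueError("target_proportion must lie in (0, 1]")


@dataclass(frozen=True)
class LeavingRule:
    """Parameterized quitting rule."""

    kind: str  # mvt | giving_up_time | fixed_count | random
    param: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("mvt", "giving_up_time", "fixed_count", "random"):
            raise ValueError(f"unknown leaving rule {self.kind!r}")
        if self.param <= 0:
            raise ValueError("rule parameter must be positive")


@dataclass(frozen=True)
class AgentConfig:
    """Collection strategy, pick-time model and quitting rule."""

    strategy: str = "nearest_neighbor"  # nearest_neighbor | scanner | random
    disorder: float = 0.0  # ε ∈ [0, 1]: probability of a random pick
    base_latency: float = 0.3  # s per pick before movement time
    move_speed: float = 1000.0  # px/s effective hand/eye speed
    noise_sd: float = 0.2  # sd of multiplicative lognormal pick-time noise
    rule: LeavingRule = field(default_factory=lambda: LeavingRule("mvt", 1.0))
    min_picks: int = 3
    distractor_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in ("nearest_neighbor", "scanner", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.disorder <= 1.0:
            raise ValueError("disorder must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What actually generated a trial, for recovery tests."""

    trial_id: str
    seed: int
    arena: dict
    agent: dict
    target_proportion: float
    rule_evaluations: list[dict] = field(default_factory=list)
    depleted: bool = False


@dataclass
class Session:
    """A sequence of simulated trials with inter-patch travel metadata."""

    trials: list[Trial]
    ground_truths: list[GroundTruth]
    travel_cost_s: float = TRAVEL_COST_S
    seed: int | None = None


class _Items:
    """Item positions drifting at constant speed with wall reflection and
    direction redraws at per-item semi-random intervals."""

    def __init__(self, n, arena: ArenaConfig, rng: np.random.Generator):
        self.arena = arena
        self.pos = np.column_stack(
            [rng.uniform(0, arena.width, n), rng.uniform(0, arena.height, n)]
        )
        angles = rng.uniform(0, 2 * math.pi, n)
        self.vel = arena.speed * np.column_stack([np.cos(angles), np.sin(angles)])
        lo, hi = arena.direction_change_bounds
        self.next_change = rng.uniform(lo, hi, n)
        self.rng = rng
        self.t = 0.0

    def advance(self, t_new: float) -> None:
        if self.arena.speed == 0 or t_new <= self.t:
            self.t = max(self.t, t_new)
            return
        lo, hi = self.arena.direction_change_bounds
        for i in range(len(self.pos)):
            t = self.t
            while t < t_new:
                step_end = min(self.next_change[i], t_new)
                self._move(i, step_end - t)
                t = step_end
                if step_end >= self.next_change[i] - 1e-12 and step_end < t_new:
                    angle = self.rng.uniform(0, 2 * math.pi)
                    self.vel[i] = self.arena.speed * np.array(
                        [math.cos(angle), math.sin(angle)]
                    )
                    self.next_change[i] = step_end + self.rng.uniform(lo, hi)
        self.t = t_new

    def _move(self, i: int, dt: float) -> None:
        for axis, limit in ((0, self.arena.width), (1, self.arena.height)):
            x = self.pos[i, axis] + self.vel[i, axis] * dt
            # fold into [0, 2L) then mirror: elastic reflection at walls
            x = x % (2 * limit)
            if x > limit:
                x = 2 * limit - x
                self.vel[i, axis] = -abs(self.vel[i, axis])
            self.pos[i, axis] = x


def _riair_at(times: list[float]) -> float:
    """Items-mode RIAIR at the latest pick (same arithmetic as the rates
    module: instantaneous 1/Δt over average n/t)."""
    n = len(times)
    prev = times[-2] if n > 1 else 0.0
    inst = 1.0 / (times[-1] - prev)
    avg = n / times[-1]
    return inst / avg


def simulate_trial(
    arena: ArenaConfig,
    agent: AgentConfig,
    seed: int,
    trial_id: str = "t0",
    participant_id: str = "sim",
    condition: str = "sim",
    age_group: str = "agent",
    session_id: str = "sim",
) -> tuple[Trial, GroundTruth]:
    """Simulate one patch visit; identical seed + configs give an
    identical event log."""
    rng = np.random.default_rng(seed)
    prop = (
        arena.target_proportion
        if arena.target_proportion is not None
        else rng.uniform(0.20, 0.30)
    )
    n_targets = max(1, round(prop * arena.set_size))
    items = _Items(arena.set_size, arena, rng)
    is_target = np.zeros(arena.set_size, dtype=bool)
    is_target[rng.choice(arena.set_size, n_targets, replace=False)] = True

    if agent.strategy == "scanner":
        # noisy reading order over initial positions: row bands top-to-bottom,
        # left-to-right within a band; disorder blurs the band assignment
        noise = agent.disorder * arena.height / 4.0
        keys = (
            np.round((items.pos[:, 1] + rng.normal(0, noise + 1e-9, arena.set_size))
                     / (arena.height / 8.0)),
            items.pos[:, 0],
        )
        scan_rank = np.lexsort((keys[1], keys[0]))
        scan_order = {int(idx): r for r, idx in enumerate(scan_rank)}

    remaining = set(np.flatnonzero(is_target).tolist())
    agent_pos = np.array([arena.width / 2.0, arena.height / 2.0])
    t = 0.0
    events: list[PickEvent] = []
    pick_times: list[float] = []
    evaluations: list[dict] = []
    depleted = False

    while remaining:
        cand = sorted(remaining)
        dists = np.linalg.norm(items.pos[cand] - agent_pos, axis=1)
        if agent.strategy == "random" or rng.random() < agent.disorder:
            choice = cand[rng.integers(len(cand))]
        elif agent.strategy == "scanner":
            choice = min(cand, key=lambda i: scan_order[i])
        else:
            choice = cand[int(np.argmin(dists))]
        dist = float(np.linalg.norm(items.pos[choice] - agent_pos))

        expected_dt = agent.base_latency + dist / agent.move_speed
        if agent.rule.kind == "giving_up_time" and pick_times:
            if expected_dt > agent.rule.param and len(pick_times) >= agent.min_picks:
                evaluations.append(
                    {"n": len(pick_times), "anticipated_dt": expected_dt,
                     "leave": True}
                )
                break

        dt = expected_dt * float(rng.lognormal(0.0, agent.noise_sd))
        t += dt
        items.advance(t)
        x, y = items.pos[choice]  # position at the collection instant
        events.append(
            PickEvent(
                index=len(events) + 1,
                t=t,
                x=float(x),
                y=float(y),
                kind="target",
                points=TARGET_POINTS,
            )
        )
        pick_times.append(t)
        remaining.discard(choice)
        agent_pos = np.array([x, y])

        n = len(pick_times)
        leave = False
        info: dict = {"n": n}
        if agent.rule.kind == "mvt":
            riair = _riair_at(pick_times)
            info["riair"] = riair
            leave = n >= agent.min_picks and riair < agent.rule.param
        elif agent.rule.kind == "fixed_count":
            leave = n >= agent.rule.param
        elif agent.rule.kind == "random":
            leave = n >= agent.min_picks and rng.random() < agent.rule.param
        info["leave"] = leave
        evaluations.append(info)
        if leave:
            break
    else:
        depleted = True

    if not remaining:
        depleted = True

    leave_time = t + agent.base_latency
    trial = Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=condition,
        age_group=age_group,
        set_size=arena.set_size,
        events=events,
        leave_time=leave_time,
        depleted=depleted,
        session_id=session_id,
    )
    truth = GroundTruth(
        trial_id=trial_id,
        seed=seed,
        arena=asdict(arena),
        agent=asdict(agent),
        target_proportion=float(prop),
        rule_evaluations=evaluations,
        depleted=depleted,
    )
    return trial, truth


@dataclass(frozen=True)
class DesignCell:
    """One block of a session design: a participant running ``n_trials``
    under one arena/agent configuration."""

    arena: ArenaConfig
    agent: AgentConfig
    n_trials: int
    participant_id: str = "sim"
    condition: str = "sim"
    age_group: str = "agent"


def simulate_session(design: list[DesignCell], seed: int) -> Session:
    """Concatenate simulated trials across design cells.  Trials are
    separated by the fixed 2-s travel cost, recorded as session metadata
    (never on any trial's clock)."""
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    trials, truths = [], []
    for c, cell in enumerate(design):
        for k in range(cell.n_trials):
            sub = int(rng.integers(0, 2**31 - 1))
            trial, truth = simulate_trial(
                cell.arena,
                cell.agent,
                seed=sub,
                trial_id=f"c{c}_t{k}",
                participant_id=cell.participant_id,
                condition=cell.condition,
                age_group=cell.age_group,
                session_id=f"s{seed}",
            )
            trials.append(trial)
            truths.append(truth)
    return Session(trials=trials, ground_truths=truths, seed=seed)


def simulate_cohort(
    arena: ArenaConfig,
    agent: AgentConfig,
    n_agents: int,
    trials_per_agent: int,
    seed: int,
    condition: str = "sim",
    age_group: str = "agent",
) -> Session:
    """A cohort of ``n_agents`` simulated participants, each foraging
    ``trials_per_agent`` patches under the same configuration."""
    design = [
        DesignCell(
            arena=arena,
            agent=agent,
            n_trials=trials_per_agent,
            participant_id=f"agent{p:03d}",
            condition=condition,
            age_group=age_group,
        )
        for p in range(n_agents)
    ]
    return simulate_session(design, seed)
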
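"""The cooperation-trial state machine.

A session is replayed sample by sample on a shared uniform time grid.  A
trial arms when every subject is in the start zone A, becomes active when
any subject leaves A, and succeeds when all subjects are simultaneously in
the reward zone C after each has progressed A → B → C within the trial.
A success emits a reward event (pump activation); the pair must return to
A to arm the next trial.  An active trial fails the moment the subjects
are two zones apart (A and C), or once they have occupied different zones
for strictly more than ``max_mismatch_s`` continuous seconds.  The session
ends at ``max_rewarded_trials`` successes or ``max_session_s`` elapsed
time, whichever comes first.

In solitary mode the partner-dependent rules degenerate to the single
subject's own zone: success is its own A → B → C traversal, re-arming its
own return to A, and the mismatch/two-apart rules never fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import numpy as np

from .maze_model import EngineParams, MazeGeometry, zone_distance, zone_sequence
from .track_io import Event, EventLog, SessionTracks

__all__ = [
    "PRE_ARMED",
    "ARMED",
    "ACTIVE",
    "BROKEN",
    "DONE",
    "EngineState",
    "TrialRecord",
    "SessionResult",
    "step",
    "run_session",
]

# engine phases
PRE_ARMED = "pre_armed"   # waiting for the first simultaneous A occupancy
ARMED = "armed"           # all subjects in A, trial ready
ACTIVE = "active"         # trial running, coordination rules enforced
BROKEN = "broken"         # after an outcome; waiting for re-arm, rules suspended
DONE = "done"             # session over; absorbing

# comparisons against the mismatch window and the session clock tolerate
# accumulated binary-float error; the margin is far below one sample
_EPS = 1e-9

BREAK_CAUSES = ("mismatch_timeout", "two_zones_apart", "session_end")


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class TrialRecord:
    """One armed trial and its outcome."""

    t_armed: float
    t_outcome: float
    outcome: str                 # "reward" | "break"
    cause: str = ""              # for breaks: one of BREAK_CAUSES

    def __post_init__(self) -> None:
        if self.t_outcome < self.t_armed:
            raise ValueError("t_outcome must be >= t_armed")
        if self.outcome == "break" and self.cause not in BREAK_CAUSES:
            raise ValueError(f"unknown break cause {self.cause!r}")


@dataclass
class EngineState:
    """Mutable engine state folded over the sample grid by :func:`step`."""

    params: EngineParams
    phase: str = PRE_ARMED
    t_now: float = 0.0
    t_armed: float = nan
    mismatch_elapsed_s: float = 0.0
    rewards_so_far: int = 0
    # per-subject progression flags within the current trial
    seen_b: list[bool] = field(default_factory=list)
    first_c: list[bool] = field(default_factory=list)
    abc_ok: list[bool] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    scored_duration_s: float = nan

    def _reset_flags(self) -> None:
        n = self.params.n_subjects
        self.seen_b = [False] * n
        self.first_c = [False] * n
        self.abc_ok = [False] * n


@dataclass
class SessionResult:
    """Event log plus trial records for one scored session."""

    events: EventLog
    trials: list[TrialRecord]
    scored_duration_s: float
    params: EngineParams
    session_id: str = ""
    day_index: int = 0
    pair_id: str = ""

    @property
    def n_rewards(self) -> int:
        return sum(1 for tr in self.trials if tr.outcome == "reward")

    @property
    def n_breaks(self) -> int:
        return sum(1 for tr in self.trials if tr.outcome == "break")


def _arm(state: EngineState, t_s: float, zones: tuple[str, ...], events: list[Event]) -> None:
    state.phase = ARMED
    state.t_armed = t_s
    state.mismatch_elapsed_s = 0.0
    state._reset_flags()
    events.append(Event(t_s=t_s, kind="trial_armed", zones=zones))


def _finish(state: EngineState, t_end: float, zones: tuple[str, ...], events: list[Event]) -> None:
    if state.phase == ACTIVE:
        state.trials.append(
            TrialRecord(state.t_armed, t_end, "break", "session_end")
        )
    state.phase = DONE
    state.scored_duration_s = t_end
    events.append(Event(t_s=t_end, kind="session_end", zones=zones))


def _break(state: EngineState, t_s: float, cause: str, zones: tuple[str, ...], events: list[Event]) -> None:
    state.trials.append(TrialRecord(state.t_armed, t_s, "break", cause))
    state.phase = BROKEN
    state.mismatch_elapsed_s = 0.0
    events.append(Event(t_s=t_s, kind="break", zones=zones, cause=cause))


def step(
    state: EngineState,
    zones: tuple[str, ...],
    t_s: float,
    dt_s: float,
) -> list[Event]:
    """Advance the engine by one grid sample; return the events emitted.

    Rule precedence at a sample is fixed: session caps, then the
    two-zones-apart break, then the mismatch timeout, then the reward.
    """
    if state.phase == DONE:
        raise EngineError(f"step at t={t_s}: session already ended")
    p = state.params
    if len(zones) != p.n_subjects:
        raise EngineError(
            f"step at t={t_s}: got {len(zones)} zones for mode {p.mode!r}"
        )
    for z in zones:
        if z not in ("A", "B", "C"):
            raise EngineError(f"step at t={t_s}: invalid zone label {z!r}")

    state.t_now = t_s
    events: list[Event] = []

    # session time cap — checked before anything else at this sample
    if t_s >= p.max_session_s - _EPS:
        t_end = min(t_s, p.max_session_s)
        if abs(t_end - p.max_session_s) < 1e-6:
            t_end = p.max_session_s
        _finish(state, t_end, zones, events)
        return events

    all_a = all(z == "A" for z in zones)

    if state.phase in (PRE_ARMED, BROKEN):
        if all_a:
            _arm(state, t_s, zones, events)
        return events

    if state.phase == ARMED:
        if all_a:
            return events
        # any subject left A: trial becomes active; this sample is scored
        state.phase = ACTIVE
        state.mismatch_elapsed_s = 0.0
        state._reset_flags()

    # --- ACTIVE ---
    if all_a:
        # both subjects back at the start: restart the trial in place
        _arm(state, t_s, zones, events)
        return events

    # progression flags: a subject's first C entry only counts if a B dwell
    # (after an A start) preceded it within this trial
    for i, z in enumerate(zones):
        if z == "B":
            state.seen_b[i] = True
        elif z == "C" and not state.first_c[i]:
            state.first_c[i] = True
            state.abc_ok[i] = state.seen_b[i]

    if len(zones) == 2:
        d = zone_distance(zones[0], zones[1])
        if d == 2:
            _break(state, t_s, "two_zones_apart", zones, events)
            return events
        if d > 0:
            state.mismatch_elapsed_s += dt_s
            if state.mismatch_elapsed_s > p.max_mismatch_s + _EPS:
                _break(state, t_s, "mismatch_timeout", zones, events)
                return events
        else:
            state.mismatch_elapsed_s = 0.0

    if all(z == "C" for z in zones) and all(state.abc_ok):
        state.trials.append(TrialRecord(state.t_armed, t_s, "reward"))
        state.rewards_so_far += 1
        state.phase = BROKEN  # rules suspended until re-arm
        state.mismatch_elapsed_s = 0.0
        events.append(
            Event(
                t_s=t_s,
                kind="reward",
                zones=zones,
                reward_volume_ul=p.reward_volume_ul,
                pump_duration_s=p.pump_duration_s,
            )
        )
        if state.rewards_so_far >= p.max_rewarded_trials:
            _finish(state, t_s, zones, events)
    return events


def run_session(
    tracks: SessionTracks,
    params: EngineParams | None = None,
    geom: MazeGeometry | None = None,
) -> SessionResult:
    """Score a whole session by folding :func:`step` over the sample grid."""
    params = params or EngineParams(mode=tracks.condition.mode)
    geom = geom or MazeGeometry()
    if tracks.n_subjects != params.n_subjects:
        raise EngineError(
            f"{params.mode} mode requires {params.n_subjects} subject(s), "
            f"found {tracks.n_subjects}"
        )
    if not tracks.on_common_grid():
        raise EngineError(
            "tracks are not on a shared uniform grid; resample() them first"
        )

    subjects = tracks.subjects
    zone_arrays = [
        zone_sequence(tracks.subject(s)["x_cm"].to_numpy(), geom) for s in subjects
    ]
    t = tracks.subject(subjects[0])["time_s"].to_numpy()
    n = len(t)

    state = EngineState(params=params)
    log = EventLog()
    if params.n_subjects == 2:
        z0, z1 = (z.tolist() for z in zone_arrays)  # plain str, faster loop
        zones_iter = [(z0[i], z1[i]) for i in range(n)]
    else:
        zones_iter = [(z,) for z in zone_arrays[0].tolist()]

    t_prev = t[0] if n else 0.0
    for i in range(n):
        dt = t[i] - t_prev
        t_prev = t[i]
        for ev in step(state, zones_iter[i], float(t[i]), float(dt)):
            log.append(ev)
        if state.phase == DONE:
            break
    if state.phase != DONE:
        # track record exhausted before any cap: session ends at the last sample
        events: list[Event] = []
        _finish(state, float(t[-1]) if n else 0.0, zones_iter[-1] if n else (), events)
        for ev in events:
            log.append(ev)

    return SessionResult(
        events=log,
        trials=state.trials,
        scored_duration_s=state.scored_duration_s,
        params=params,
        session_id=tracks.session_id,
        day_index=tracks.day_index,
        pair_id=tracks.pair_id,
    )
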
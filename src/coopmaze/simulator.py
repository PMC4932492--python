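"""Coupled stochastic-agent simulator of cooperation-maze sessions.

Each subject is a one-dimensional agent on the maze's long axis cycling
through four behavioral states:

* **deciding** — pacing inside the start zone A.  A re-decision timer
  (exponential, mean ``redecide_mean_s``) fires repeatedly; at each firing
  the agent commits to a reward run with probability
  ``commit_base + (1 − commit_base) × effective coupling`` (a paired
  agent initiates when it attends to its partner; a solitary agent's
  commitment uses its own task skill instead).  An uncommitted agent that
  gets pulled out of zone A by its partner commits implicitly — it is
  following.
* **run to C** — Euler–Maruyama update: velocity is ``goal_gain · speed``
  toward the reward wall, plus a bounded (tanh-saturating) attraction
  toward the partner scaled by the effective coupling, plus Gaussian
  noise of scale ``noise_sd``.
* **drinking** — a fixed dwell at the reward wall (consuming the reward,
  waiting for the partner), then
* **return to A** — the same dynamics aimed at the start wall, closing
  the loop back to *deciding*.

Learning is exponential saturation per individual: ``goal_gain`` (task
skill — knowing to shuttle wall-to-wall) and ``coupling`` (social skill —
attending to the partner) rise with an individual's days of training.
The effective coupling additionally carries a pair-familiarity factor
that grows with days spent with the *current* partner, a divider factor
(which sensory channels connect the lanes), and a contextual-cue penalty
(attention diverted to wall patterns).  Because individual skill persists
while familiarity resets, replacing a partner after training produces a
temporary performance dip that stays well above naive performance — the
latent-learning signature — without any hard-coded day effect.

Lateral position is decorative jitter about the lane center; scoring
depends only on the longitudinal coordinate.  All randomness flows from
one master seed through per-arm/pair/day substreams, so any single
session is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, sqrt, tanh
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maze_model import ConditionSpec, EngineParams, MazeGeometry
from .metrics import MetricRow, session_metrics
from .track_io import SessionTracks
from .trial_engine import run_session

__all__ = [
    "AgentParams",
    "PairScenario",
    "ExperimentPlan",
    "DEFAULT_DIVIDER_COUPLING",
    "simulate_session",
    "simulate_solitary",
    "simulate_experiment",
    "demo_plan",
]

#: Effective-coupling multiplier per divider build.  Values encode only the
#: observed performance ordering (all-modality best, vision next, opaque
#: builds worst and similar), not measured effect sizes.
DEFAULT_DIVIDER_COUPLING: Mapping[str, float] = {
    "transparent_perforated": 1.0,
    "transparent": 0.7,
    "sealed": 0.4,
    "perforated": 0.35,
}

#: Speed multiplier per sex label; the sex contrast is modeled purely as a
#: locomotor-activity difference (females run more), with diffusion scaled
#: alongside speed so path efficiency is preserved.
DEFAULT_SEX_SPEED: Mapping[str, float] = {
    "female": 1.25,
    "male": 1.0,
    "unspecified": 1.0,
}

_REACH_TOL_CM = 3.0      # how close to a wall counts as "reached"
_SAT_CM = 30.0           # separation scale of the saturating attraction


def _saturating(day0: float, asymptote: float, rate: float, experience_days: float) -> float:
    """Exponential-saturation learning curve, clipped to [0, 1]."""
    v = asymptote - (asymptote - day0) * exp(-rate * max(experience_days, 0.0))
    return min(max(v, 0.0), 1.0)


@dataclass(frozen=True)
class AgentParams:
    """One subject's locomotor and learning parameters.

    ``speed_cm_s`` is the full-commitment progression speed; the realised
    drift is ``goal_gain × speed``.  ``goal_gain`` and ``coupling`` give
    the day-1 values, each rising toward its asymptote at its learn rate
    (per day of that individual's training).  ``drink_pause_s`` is the
    dwell at the reward wall (drinking, waiting) before heading back.
    """

    speed_cm_s: float = 14.0
    noise_sd: float = 3.0            # cm / sqrt(s)
    coupling: float = 0.10
    coupling_asymptote: float = 0.95
    coupling_learn_rate: float = 0.18
    goal_gain: float = 0.12
    goal_gain_asymptote: float = 0.85
    goal_gain_learn_rate: float = 0.13
    drink_pause_s: float = 8.0
    commit_base: float = 0.05        # floor of the per-decision commit probability
    redecide_mean_s: float = 8.0     # mean interval between commit decisions
    pace_frac: float = 0.8           # pacing speed as a fraction of the run drift

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0 or not 0.0 <= self.coupling_asymptote <= 1.0:
            raise ValueError("coupling values must lie in [0, 1]")
        if self.speed_cm_s < 0 or self.noise_sd < 0 or self.drink_pause_s < 0:
            raise ValueError("speeds, noise and pauses must be >= 0")

    def goal_gain_on(self, experience_days: float) -> float:
        return _saturating(
            self.goal_gain, self.goal_gain_asymptote,
            self.goal_gain_learn_rate, experience_days,
        )

    def coupling_on(self, experience_days: float) -> float:
        return _saturating(
            self.coupling, self.coupling_asymptote,
            self.coupling_learn_rate, experience_days,
        )


@dataclass(frozen=True)
class PairScenario:
    """Full parameterization of one simulated session.

    ``experience_days`` (per agent) and ``familiarity_days`` default to
    ``day − 1`` when left ``None``; an experiment driver overrides them to
    express partner swaps (individual experience keeps accumulating while
    familiarity restarts with the new partner).
    """

    agents: tuple[AgentParams, ...] = (AgentParams(), AgentParams())
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    divider_coupling_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVIDER_COUPLING)
    )
    context_coupling_penalty: float = 0.35
    sex_speed_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_SPEED)
    )
    familiarity_floor: float = 0.5
    familiarity_learn_rate: float = 0.6
    session_s: float = 900.0
    dt_s: float = 0.1
    seed: int = 0
    experience_days: tuple[float, ...] | None = None
    familiarity_days: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.agents) <= 2:
            raise ValueError("a scenario holds 1 or 2 agents")
        for m in self.divider_coupling_multiplier.values():
            if not 0.0 < m <= 1.0:
                raise ValueError("divider multipliers must lie in (0, 1]")
        if not 0.0 <= self.context_coupling_penalty < 1.0:
            raise ValueError("context_coupling_penalty must lie in [0, 1)")
        if self.dt_s <= 0 or self.session_s <= 0:
            raise ValueError("dt_s and session_s must be strictly positive")

    def effective_coupling(self, agent: AgentParams, experience_days: float,
                           familiarity_days: float) -> float:
        fam = 1.0 - (1.0 - self.familiarity_floor) * exp(
            -self.familiarity_learn_rate * max(familiarity_days, 0.0)
        )
        c = agent.coupling_on(experience_days) * fam
        c *= self.divider_coupling_multiplier[self.condition.divider]
        if self.condition.context_cues:
            c *= 1.0 - self.context_coupling_penalty
        return c


@dataclass(frozen=True)
class ExperimentPlan:
    """A multi-day, multi-pair experiment across one or more condition arms.

    ``swap_day`` (1-based, optional) re-pairs the trained individuals from
    that day on: pair *i* keeps its first subject and receives the second
    subject of pair *i*+1 (cyclically), so every subject stays trained but
    every pair is new.
    """

    n_pairs: int = 11
    days: int = 18
    swap_day: int | None = None
    arms: tuple[ConditionSpec, ...] = (ConditionSpec(),)
    seed: int = 0
    agent_template: AgentParams = AgentParams()
    scenario_template: PairScenario = PairScenario()
    heterogeneity_sd: float = 0.08   # lognormal sd of per-individual multipliers

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.days < 1:
            raise ValueError("n_pairs and days must be >= 1")
        if self.swap_day is not None and not 1 <= self.swap_day <= self.days:
            raise ValueError("swap_day must fall within the day range")


def _session_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *key]))


# behavioral states of one agent
_DECIDING, _TO_C, _DRINK, _TO_A = 0, 1, 2, 3


def _simulate(scenario: PairScenario, day: int, n_agents: int) -> SessionTracks:
    geom = MazeGeometry()
    length = geom.length_cm
    a_zone_end = geom.zone_bounds_cm[0]
    dt = scenario.dt_s
    n = int(round(scenario.session_s / dt)) + 1
    rng = np.random.default_rng(scenario.seed)

    exp_days = scenario.experience_days
    if exp_days is None:
        exp_days = (float(day - 1),) * n_agents
    fam_days = scenario.familiarity_days
    if fam_days is None:
        fam_days = float(day - 1)

    agents = scenario.agents[:n_agents]
    sex_mult = scenario.sex_speed_multiplier.get(scenario.condition.sex, 1.0)
    speeds = [a.speed_cm_s * sex_mult for a in agents]
    noise_sds = [a.noise_sd * sex_mult for a in agents]
    gains = [a.goal_gain_on(exp_days[i]) for i, a in enumerate(agents)]
    couplings = [
        scenario.effective_coupling(a, exp_days[i], fam_days) if n_agents == 2 else 0.0
        for i, a in enumerate(agents)
    ]
    # a solitary subject's initiative rests on its own task skill; a paired
    # subject's on its attention to the partner
    commit_p = [
        a.commit_base + (1.0 - a.commit_base)
        * (couplings[i] if n_agents == 2 else gains[i])
        for i, a in enumerate(agents)
    ]

    noise = rng.standard_normal((n, n_agents))
    for i in range(n_agents):
        noise[:, i] *= noise_sds[i] * sqrt(dt)

    x = np.empty((n, n_agents))
    pos = [0.0] * n_agents            # everyone starts at the A wall
    state = [_DECIDING] * n_agents
    timer = [float(rng.exponential(agents[i].redecide_mean_s)) for i in range(n_agents)]
    pace_target = [float(rng.uniform(5.0, a_zone_end - 5.0)) for _ in range(n_agents)]
    inv_sat = 1.0 / _SAT_CM

    for k in range(n):
        for i in range(n_agents):
            x[k, i] = pos[i]
        for i in range(n_agents):
            a = agents[i]
            st = state[i]
            if st == _DRINK:
                timer[i] -= dt
                if timer[i] <= 0.0:
                    state[i] = _TO_A
                continue
            pull = (
                couplings[i] * speeds[i] * tanh((pos[1 - i] - pos[i]) * inv_sat)
                if n_agents == 2
                else 0.0
            )
            if st == _DECIDING:
                # pace inside zone A until a commit decision (or the partner
                # drags the agent out, which counts as following)
                timer[i] -= dt
                if timer[i] <= 0.0:
                    timer[i] = float(rng.exponential(a.redecide_mean_s))
                    if rng.random() < commit_p[i]:
                        state[i] = _TO_C
                        st = _TO_C
                if st == _DECIDING:
                    d = pace_target[i] - pos[i]
                    v = a.pace_frac * gains[i] * speeds[i] * (1.0 if d > 0 else -1.0)
                    if abs(d) < 3.0:
                        pace_target[i] = float(rng.uniform(5.0, a_zone_end - 5.0))
                    v += pull
            if st == _TO_C:
                v = gains[i] * speeds[i] + pull
            elif st == _TO_A:
                v = -gains[i] * speeds[i] + pull
            p = pos[i] + v * dt + noise[k, i]
            if p < 0.0:
                p = 0.0
            elif p > length:
                p = length
            pos[i] = p
            if st == _DECIDING and p >= a_zone_end:
                state[i] = _TO_C         # pulled into B: following the partner
            elif st == _TO_C and p >= length - _REACH_TOL_CM:
                state[i] = _DRINK
                timer[i] = a.drink_pause_s
            elif st == _TO_A and p <= _REACH_TOL_CM:
                state[i] = _DECIDING
                timer[i] = float(rng.exponential(a.redecide_mean_s))
                pace_target[i] = float(rng.uniform(5.0, a_zone_end - 5.0))

    t = np.arange(n) * dt
    frames = []
    for i in range(n_agents):
        lane = geom.lane_center_cm(min(i, geom.n_lanes - 1))
        wiggle = np.clip(
            np.cumsum(rng.normal(0.0, 0.08, n)), -5.0, 5.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "subject_id": f"rat{i + 1}",
                    "x_cm": x[:, i],
                    "y_cm": lane + wiggle,
                }
            )
        )
    mode = "paired" if n_agents == 2 else "solitary"
    cond = scenario.condition
    if cond.mode != mode:
        cond = replace(cond, mode=mode)
    return SessionTracks(
        data=pd.concat(frames, ignore_index=True),
        condition=cond,
        dt_s=dt,
        day_index=day,
    )


def simulate_session(scenario: PairScenario, day: int = 1) -> SessionTracks:
    """Simulate one paired session on training day ``day`` (1-based)."""
    if len(scenario.agents) != 2:
        raise ValueError("simulate_session needs a two-agent scenario")
    return _simulate(scenario, day, 2)


def simulate_solitary(scenario: PairScenario, day: int = 1) -> SessionTracks:
    """Simulate one solitary session; partner coupling is ignored."""
    return _simulate(scenario, day, 1)


def _individual_params(plan: ExperimentPlan, arm_idx: int) -> list[list[AgentParams]]:
    """Draw mildly heterogeneous per-individual parameters (2 per pair)."""
    rng = _session_rng(plan.seed, arm_idx, 7919)
    out = []
    for _ in range(plan.n_pairs):
        pair = []
        for _ in range(2):
            m_speed = float(rng.lognormal(0.0, plan.heterogeneity_sd))
            m_rate = float(rng.lognormal(0.0, plan.heterogeneity_sd))
            a = plan.agent_template
            pair.append(
                replace(
                    a,
                    speed_cm_s=a.speed_cm_s * m_speed,
                    noise_sd=a.noise_sd * m_speed,
                    goal_gain_learn_rate=a.goal_gain_learn_rate * m_rate,
                    coupling_learn_rate=a.coupling_learn_rate * m_rate,
                )
            )
        out.append(pair)
    return out


def simulate_experiment(plan: ExperimentPlan) -> list[MetricRow]:
    """Run every arm × pair × day, scoring each session through the engine.

    Returns one :class:`~coopmaze.metrics.MetricRow` per session.  After
    ``swap_day`` the individuals are re-paired (skills persist, pair
    familiarity restarts), which is what exposes latent social learning.
    """
    rows: list[MetricRow] = []
    for arm_idx, condition in enumerate(plan.arms):
        individuals = _individual_params(plan, arm_idx)
        solitary = condition.mode == "solitary"
        for day in range(1, plan.days + 1):
            swapped = plan.swap_day is not None and day >= plan.swap_day
            for p in range(plan.n_pairs):
                if swapped and not solitary:
                    agents = (
                        individuals[p][0],
                        individuals[(p + 1) % plan.n_pairs][1],
                    )
                    fam_days = float(day - plan.swap_day)
                else:
                    agents = tuple(individuals[p]) if not solitary else (individuals[p][0],)
                    fam_days = float(day - 1)
                seed = int(
                    np.random.SeedSequence(
                        [plan.seed, arm_idx, p, day]
                    ).generate_state(1)[0] % (2**31)
                )
                scenario = replace(
                    plan.scenario_template,
                    agents=agents,
                    condition=condition,
                    seed=seed,
                    experience_days=(float(day - 1),) * len(agents),
                    familiarity_days=fam_days,
                )
                tracks = (
                    simulate_solitary(scenario, day)
                    if solitary
                    else simulate_session(scenario, day)
                )
                tracks.pair_id = f"arm{arm_idx}-pair{p + 1}"
                params = EngineParams(mode=condition.mode)
                result = run_session(tracks, params)
                rows.append(session_metrics(result, tracks))
    return rows


def demo_plan(seed: int = 0) -> ExperimentPlan:
    """The headline protocol: 11 pairs, 18 learning days + 6 latent days
    with the partner swap on day 19, default condition."""
    return ExperimentPlan(n_pairs=11, days=24, swap_day=19, seed=seed)
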
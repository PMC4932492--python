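"""Plain-text (YAML) configuration for the engine, maze and simulator.

One flat config file feeds all subcommands: keys mirror the dataclass
fields of :class:`~coopmaze.maze_model.MazeGeometry`,
:class:`~coopmaze.maze_model.EngineParams` and
:class:`~coopmaze.maze_model.ConditionSpec`; every default is overridable.
Experiment plans use the same format with the plan's own fields plus an
optional ``arms`` list of condition mappings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .maze_model import ConditionSpec, EngineParams, MazeGeometry
from .simulator import AgentParams, ExperimentPlan, PairScenario

__all__ = ["EngineConfig", "load_config", "load_plan", "config_snapshot"]


@dataclass(frozen=True)
class EngineConfig:
    geometry: MazeGeometry = field(default_factory=MazeGeometry)
    params: EngineParams = field(default_factory=EngineParams)
    condition: ConditionSpec = field(default_factory=ConditionSpec)


def _field_names(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def _build(cls, data: Mapping[str, Any], used: set[str]):
    names = _field_names(cls)
    kwargs = {}
    for key, value in data.items():
        if key in names:
            f = next(f for f in fields(cls) if f.name == key)
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
            used.add(key)
    return cls(**kwargs)


def load_config(path: str | Path | None) -> EngineConfig:
    """Read a flat YAML config; missing file/None yields pure defaults."""
    if path is None:
        return EngineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of flat keys")
    used: set[str] = set()
    geom = _build(MazeGeometry, raw, used)
    params = _build(EngineParams, raw, used)
    cond = _build(ConditionSpec, raw, used)
    # "mode" belongs to both params and condition; keep them coherent
    unknown = set(raw) - used
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if params.mode != cond.mode:
        cond = ConditionSpec(
            divider=cond.divider, context_cues=cond.context_cues,
            sex=cond.sex, mode=params.mode,
        )
    return EngineConfig(geometry=geom, params=params, condition=cond)


def load_plan(path: str | Path, seed: int | None = None) -> ExperimentPlan:
    """Read an experiment-plan YAML file.

    Recognized keys: the :class:`ExperimentPlan` fields (``n_pairs``,
    ``days``, ``swap_day``, ``seed``, ``heterogeneity_sd``), ``agent``
    (mapping of :class:`AgentParams` fields), ``scenario`` (mapping of
    :class:`PairScenario` fields), and ``arms`` (list of
    :class:`ConditionSpec` mappings; default one default-condition arm).
    A ``seed`` argument overrides the file's seed.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: plan must be a mapping")
    used: set[str] = set()
    agent = _build(AgentParams, raw.get("agent", {}), set())
    scen_kwargs = dict(raw.get("scenario", {}))
    scenario = _build(PairScenario, scen_kwargs, set())
    arms_raw = raw.get("arms")
    if arms_raw:
        arms = tuple(_build(ConditionSpec, a, set()) for a in arms_raw)
    else:
        arms = (ConditionSpec(),)
    plan_keys = {
        k: v for k, v in raw.items() if k not in ("agent", "scenario", "arms")
    }
    plan = _build(ExperimentPlan, plan_keys, used)
    unknown = set(plan_keys) - used
    if unknown:
        raise ValueError(f"{path}: unknown plan keys {sorted(unknown)}")
    if seed is not None:
        plan = ExperimentPlan(
            n_pairs=plan.n_pairs, days=plan.days, swap_day=plan.swap_day,
            arms=arms, seed=int(seed), agent_template=agent,
            scenario_template=scenario, heterogeneity_sd=plan.heterogeneity_sd,
        )
    else:
        plan = ExperimentPlan(
            n_pairs=plan.n_pairs, days=plan.days, swap_day=plan.swap_day,
            arms=arms, seed=plan.seed, agent_template=agent,
            scenario_template=scenario, heterogeneity_sd=plan.heterogeneity_sd,
        )
    return plan


def config_snapshot(cfg: EngineConfig) -> dict:
    """JSON-serializable snapshot of a config (for run manifests)."""
    from dataclasses import asdict

    return {
        "geometry": asdict(cfg.geometry),
        "params": asdict(cfg.params),
        "condition": asdict(cfg.condition),
    }
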
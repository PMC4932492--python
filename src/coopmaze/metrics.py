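"""Per-session behavioral measures and learning-curve aggregation.

Four measures per scored session:

* **rewards** — the number of mutual-reward events in the session log;
* **activity** — total distance moved (cm), summed over the pair;
* **efficacy** — rewards per cm of activity, the utility of cooperation
  (a pair that earns the same rewards while running less is more
  efficacious);
* **latency** — time from session start to the pair's first simultaneous
  arrival in the reward zone C (first C entry in solitary mode), missing
  when the pair never gets there.

Sessions aggregate across pairs into per-day mean ± SEM learning curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import nan, sqrt

import numpy as np
import pandas as pd

from .maze_model import MazeGeometry, zones_of
from .track_io import SessionTracks
from .trial_engine import SessionResult

__all__ = [
    "MetricRow",
    "path_length",
    "session_metrics",
    "metric_frame",
    "aggregate_days",
    "percent_change",
]

METRICS = ("rewards", "activity_cm", "efficacy", "latency_s")


@dataclass(frozen=True)
class MetricRow:
    """One session's metrics for one pair (or solitary subject)."""

    pair_id: str
    day_index: int
    condition: str
    rewards: int
    activity_cm: float
    efficacy: float
    latency_s: float            # nan = censored (no C arrival)
    scored_duration_s: float
    activity_by_subject: tuple[float, ...] = ()


def path_length(x_cm: np.ndarray, y_cm: np.ndarray | None = None) -> float:
    """Total Euclidean path length of a resampled track, in cm."""
    x = np.asarray(x_cm, dtype=float)
    if x.size < 2:
        warnings.warn("track has fewer than 2 samples; path length is 0", stacklevel=2)
        return 0.0
    dx = np.diff(x)
    if y_cm is None:
        return float(np.abs(dx).sum())
    dy = np.diff(np.asarray(y_cm, dtype=float))
    return float(np.hypot(dx, dy).sum())


def first_joint_c_time(tracks: SessionTracks, geom: MazeGeometry | None = None,
                       t_max: float | None = None) -> float:
    """Time of the first sample where every subject is in zone C, else nan."""
    geom = geom or MazeGeometry()
    subjects = tracks.subjects
    in_c = None
    for sid in subjects:
        zc = zones_of(tracks.subject(sid)["x_cm"].to_numpy(), geom) == "C"
        in_c = zc if in_c is None else (in_c & zc)
    t = tracks.subject(subjects[0])["time_s"].to_numpy()
    if t_max is not None:
        in_c = in_c & (t <= t_max + 1e-9)
    hits = np.flatnonzero(in_c)
    return float(t[hits[0]]) if hits.size else nan


def session_metrics(
    result: SessionResult,
    tracks: SessionTracks,
    geom: MazeGeometry | None = None,
    latency_mode: str = "first_joint_c",
) -> MetricRow:
    """Compute one MetricRow from a scored session and its tracks.

    ``latency_mode`` is ``"first_joint_c"`` (default: first simultaneous
    pair occupancy of C, whether or not it earned a reward) or
    ``"first_reward"`` (time of the first reward event).
    """
    if result.session_id != tracks.session_id:
        raise ValueError(
            f"session id mismatch: result {result.session_id!r} "
            f"vs tracks {tracks.session_id!r}"
        )
    geom = geom or MazeGeometry()
    subjects = tracks.subjects
    # only the scored part of the session counts toward activity
    t_end = result.scored_duration_s
    per_subject = []
    for sid in subjects:
        sub = tracks.subject(sid)
        keep = sub["time_s"].to_numpy() <= t_end + 1e-9
        per_subject.append(
            path_length(sub["x_cm"].to_numpy()[keep], sub["y_cm"].to_numpy()[keep])
        )
    activity = float(sum(per_subject))
    rewards = result.n_rewards
    efficacy = rewards / activity if activity > 0 else 0.0

    if latency_mode == "first_reward":
        reward_events = result.events.of_kind("reward")
        latency = reward_events[0].t_s if reward_events else nan
    elif latency_mode == "first_joint_c":
        latency = first_joint_c_time(tracks, geom, t_max=t_end)
    else:
        raise ValueError(f"unknown latency_mode {latency_mode!r}")

    return MetricRow(
        pair_id=tracks.pair_id,
        day_index=tracks.day_index,
        condition=tracks.condition.label(),
        rewards=rewards,
        activity_cm=activity,
        efficacy=efficacy,
        latency_s=latency,
        scored_duration_s=result.scored_duration_s,
        activity_by_subject=tuple(per_subject),
    )


def metric_frame(rows: list[MetricRow]) -> pd.DataFrame:
    """Long-format DataFrame of metric rows (one row per session)."""
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "day_index": r.day_index,
                "condition": r.condition,
                "rewards": r.rewards,
                "activity_cm": r.activity_cm,
                "efficacy": r.efficacy,
                "latency_s": r.latency_s,
                "scored_duration_s": r.scored_duration_s,
            }
            for r in rows
        ]
    )


def _sem(v: pd.Series) -> float:
    n = v.count()
    if n <= 1:
        return 0.0
    return float(v.std(ddof=1) / sqrt(n))


def aggregate_days(rows: list[MetricRow] | pd.DataFrame) -> pd.DataFrame:
    """Group sessions by (day, condition) into mean/SEM/n learning curves.

    Censored latencies (nan) are excluded from the latency cells with the
    per-cell n adjusted (``latency_s_n``); every other metric uses the full
    cell count.  Returns an empty frame for empty input.
    """
    df = rows if isinstance(rows, pd.DataFrame) else metric_frame(rows)
    if df.empty:
        return pd.DataFrame()
    out = []
    for (day, cond), cell in df.groupby(["day_index", "condition"], sort=True):
        rec: dict = {"day_index": day, "condition": cond, "n": len(cell)}
        for m in METRICS:
            v = cell[m]
            rec[f"{m}_mean"] = float(v.mean())     # nan-skipping for latency
            rec[f"{m}_sem"] = _sem(v)
            rec[f"{m}_n"] = int(v.count())
        out.append(rec)
    return pd.DataFrame(out)


def percent_change(
    table: pd.DataFrame,
    metric: str,
    baseline_day: int,
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-day percent reduction of a metric relative to a baseline day.

    Computes ``100 × (baseline − value) / baseline`` on the per-day means
    (positive = reduction, the convention used for latency curves), with
    the SEM propagated by the delta method from the per-day and baseline
    SEMs.
    """
    df = table
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("empty learning-curve table")
    base_rows = df[df["day_index"] == baseline_day]
    if base_rows.empty:
        raise ValueError(f"baseline day {baseline_day} not present")
    b = float(base_rows[f"{metric}_mean"].iloc[0])
    b_sem = float(base_rows[f"{metric}_sem"].iloc[0])
    if b == 0 or not np.isfinite(b):
        raise ValueError("baseline mean is zero or undefined")
    v = df[f"{metric}_mean"].to_numpy(dtype=float)
    v_sem = df[f"{metric}_sem"].to_numpy(dtype=float)
    pct = 100.0 * (b - v) / b
    # delta method on f(v, b) = 100 (b - v)/b with independent cells
    pct_sem = 100.0 * np.sqrt((v_sem / b) ** 2 + (v * b_sem / b**2) ** 2)
    return pd.DataFrame(
        {
            "day_index": df["day_index"].to_numpy(),
            "condition": df["condition"].to_numpy(),
            f"{metric}_pct_change": pct,
            f"{metric}_pct_change_sem": pct_sem,
        }
    )
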
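"""Reading, validating, resampling and writing subject tracks and event logs.

Track files are plain delimited text in long format, one row per sample per
subject, with header ``time_s,subject_id,x_cm,y_cm`` (a column mapping
accommodates other headers).  Event logs are written as CSV or JSON-lines
and round-trip losslessly.  ``fixture_from_zone_timeline`` synthesizes
tracks with an exactly known zone sequence, which is the main test surface
for the trial engine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maze_model import ConditionSpec, MazeGeometry

__all__ = [
    "TrackPoint",
    "SessionTracks",
    "Event",
    "EventLog",
    "TrackValidationError",
    "read_tracks",
    "resample",
    "write_tracks",
    "write_events",
    "read_events",
    "write_events_jsonl",
    "read_events_jsonl",
    "fixture_from_zone_timeline",
]

TRACK_COLUMNS = ("time_s", "subject_id", "x_cm", "y_cm")

EVENT_KINDS = ("trial_armed", "reward", "break", "session_end")

#: Gaps between consecutive samples longer than this are reported as
#: warnings during resampling (they are still interpolated — the engine has
#: no missing-data concept).
GAP_WARN_S = 1.0


class TrackValidationError(ValueError):
    """Raised when a track file violates the input contract."""


@dataclass(frozen=True)
class TrackPoint:
    """One tracked sample: time since session start plus maze coordinates."""

    t_s: float
    x_cm: float
    y_cm: float
    subject_id: str


@dataclass
class SessionTracks:
    """Synchronized time-stamped positions for one or two subjects.

    ``data`` is a long-format frame with columns ``time_s, subject_id,
    x_cm, y_cm``, sorted by subject then time.  ``dt_s`` is set once the
    tracks have been resampled onto a shared uniform grid (``None`` for raw
    tracker output).
    """

    data: pd.DataFrame
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    dt_s: float | None = None
    session_id: str = ""
    day_index: int = 0
    pair_id: str = ""

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def subject(self, subject_id: str) -> pd.DataFrame:
        sub = self.data[self.data["subject_id"] == subject_id]
        if sub.empty:
            raise KeyError(f"no subject {subject_id!r} in tracks")
        return sub.reset_index(drop=True)

    def on_common_grid(self) -> bool:
        """True when every subject shares one identical timestamp grid."""
        grids = [self.subject(s)["time_s"].to_numpy() for s in self.subjects]
        first = grids[0]
        return all(len(g) == len(first) and np.array_equal(g, first) for g in grids)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise TrackValidationError(f"missing track columns: {missing}")
        if (df["time_s"] < 0).any():
            i = int(df.index[df["time_s"] < 0][0])
            raise TrackValidationError(f"negative timestamp at row {i + 2}")
        if not np.isfinite(df[["time_s", "x_cm", "y_cm"]].to_numpy()).all():
            raise TrackValidationError("non-finite value in track data")
        for sid in self.subjects:
            t = self.subject(sid)["time_s"].to_numpy()
            if len(t) > 1 and (np.diff(t) <= 0).any():
                raise TrackValidationError(
                    f"timestamps for subject {sid!r} not strictly increasing"
                )
        n = self.n_subjects
        if n > 2:
            raise TrackValidationError(f"at most 2 subjects supported, found {n}")
        want = self.condition.n_subjects
        if n != want:
            raise TrackValidationError(
                f"{self.condition.mode} mode requires {want} subject(s), found {n}"
            )


@dataclass(frozen=True)
class Event:
    """One engine-emitted event.

    ``zones`` records every subject's zone at event time.  Reward events
    additionally carry the pump activation duration and delivered volume;
    break events carry their cause.
    """

    t_s: float
    kind: str
    zones: tuple[str, ...]
    cause: str = ""
    reward_volume_ul: float = float("nan")
    pump_duration_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventLog:
    """Time-ordered event records for one session."""

    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def append(self, event: Event) -> None:
        if self.events and self.events[-1].kind == "session_end":
            raise ValueError("cannot append after session_end")
        if self.events and event.t_s < self.events[-1].t_s:
            raise ValueError("events must be appended in time order")
        self.events.append(event)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            row: dict = {
                "t_s": e.t_s,
                "kind": e.kind,
                "cause": e.cause,
                "reward_volume_ul": e.reward_volume_ul,
                "pump_duration_s": e.pump_duration_s,
            }
            for i, z in enumerate(e.zones, start=1):
                row[f"zone_{i}"] = z
            rows.append(row)
        cols = ["t_s", "kind", "cause", "zone_1", "zone_2",
                "reward_volume_ul", "pump_duration_s"]
        return pd.DataFrame(rows, columns=cols)


def read_tracks(
    path: str | Path,
    condition: ConditionSpec | None = None,
    column_map: Mapping[str, str] | None = None,
    **meta,
) -> SessionTracks:
    """Read a long-format track CSV and validate it.

    ``column_map`` maps the canonical names (``time_s`` etc.) to the
    header names actually present in the file.
    """
    condition = condition or ConditionSpec()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise TrackValidationError(f"cannot parse {path}: {e}") from e
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    df = df[list(TRACK_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for sid, sub in df.groupby("subject_id"):
        t = sub["time_s"].to_numpy()
        if len(t) > 1:
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                line = int(sub.index[bad[0] + 1]) + 2  # header + 1-based
                raise TrackValidationError(
                    f"{path}: non-increasing timestamp for subject {sid!r} "
                    f"at line {line}"
                )
    df = df.sort_values(["subject_id", "time_s"], kind="mergesort").reset_index(drop=True)
    tracks = SessionTracks(data=df, condition=condition, **meta)
    tracks.validate()
    return tracks


def write_tracks(tracks: SessionTracks, path: str | Path) -> None:
    """Write tracks back out in the canonical long CSV dialect."""
    tracks.data[list(TRACK_COLUMNS)].to_csv(path, index=False)


def resample(tracks: SessionTracks, dt_s: float) -> SessionTracks:
    """Linearly interpolate all subjects onto one shared uniform grid.

    The grid runs from 0 to the earliest per-subject last timestamp in
    steps of ``dt_s`` — no extrapolation past any subject's record.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be strictly positive")
    subjects = tracks.subjects
    ends = []
    for sid in subjects:
        t = tracks.subject(sid)["time_s"].to_numpy()
        if len(t) < 2:
            raise TrackValidationError(
                f"subject {sid!r} has fewer than 2 samples; cannot resample"
            )
        ends.append(t[-1])
        gaps = np.diff(t)
        if (gaps > GAP_WARN_S).any():
            warnings.warn(
                f"subject {sid!r}: {int((gaps > GAP_WARN_S).sum())} gap(s) "
                f"longer than {GAP_WARN_S} s interpolated",
                stacklevel=2,
            )
    t_end = min(ends)
    n = int(np.floor(t_end / dt_s + 1e-9)) + 1
    if n < 1:
        raise ValueError("requested resampling grid is empty")
    grid = np.arange(n) * dt_s
    frames = []
    for sid in subjects:
        sub = tracks.subject(sid)
        t = sub["time_s"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "time_s": grid,
                    "subject_id": sid,
                    "x_cm": np.interp(grid, t, sub["x_cm"].to_numpy()),
                    "y_cm": np.interp(grid, t, sub["y_cm"].to_numpy()),
                }
            )
        )
    out = replace_tracks(tracks, pd.concat(frames, ignore_index=True), dt_s)
    return out


def replace_tracks(tracks: SessionTracks, data: pd.DataFrame, dt_s: float | None) -> SessionTracks:
    return SessionTracks(
        data=data,
        condition=tracks.condition,
        dt_s=dt_s,
        session_id=tracks.session_id,
        day_index=tracks.day_index,
        pair_id=tracks.pair_id,
    )


# ---------------------------------------------------------------------------
# event log I/O

def write_events(log: EventLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)


def read_events(path: str | Path) -> EventLog:
    df = pd.read_csv(path)
    log = EventLog()
    for _, row in df.iterrows():
        zones = tuple(
            str(row[c]) for c in ("zone_1", "zone_2")
            if c in df.columns and isinstance(row[c], str)
        )
        log.append(
            Event(
                t_s=float(row["t_s"]),
                kind=str(row["kind"]),
                zones=zones,
                cause="" if pd.isna(row.get("cause")) else str(row["cause"]),
                reward_volume_ul=float(row["reward_volume_ul"]),
                pump_duration_s=float(row["pump_duration_s"]),
            )
        )
    return log


def write_events_jsonl(log: EventLog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in log:
            rec = {
                "t_s": e.t_s,
                "kind": e.kind,
                "zones": list(e.zones),
                "cause": e.cause,
            }
            if e.kind == "reward":
                rec["reward_volume_ul"] = e.reward_volume_ul
                rec["pump_duration_s"] = e.pump_duration_s
            fh.write(json.dumps(rec) + "\n")


def read_events_jsonl(path: str | Path) -> EventLog:
    log = EventLog()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            log.append(
                Event(
                    t_s=rec["t_s"],
                    kind=rec["kind"],
                    zones=tuple(rec["zones"]),
                    cause=rec.get("cause", ""),
                    reward_volume_ul=rec.get("reward_volume_ul", float("nan")),
                    pump_duration_s=rec.get("pump_duration_s", float("nan")),
                )
            )
    return log


# ---------------------------------------------------------------------------
# fixtures

def fixture_from_zone_timeline(
    timelines: Sequence[Sequence[tuple[str, float]]],
    geom: MazeGeometry | None = None,
    dt_s: float = 0.1,
    condition: ConditionSpec | None = None,
    **meta,
) -> SessionTracks:
    """Build tracks whose zone sequence equals a requested timeline exactly.

    ``timelines`` holds, per subject, a list of ``(zone, dwell_s)`` pairs;
    every dwell must be a positive multiple of ``dt_s``.  Positions are
    placed at zone centers with an instantaneous crossing between dwells,
    so ``zone_of`` applied to the output reproduces the input timeline
    sample for sample.  All subjects must cover the same total duration so
    the result is already on a common grid.
    """
    geom = geom or MazeGeometry()
    if dt_s <= 0:
        raise ValueError("dt_s must be strictly positive")
    if not 1 <= len(timelines) <= 2:
        raise ValueError("timelines must describe 1 or 2 subjects")
    if condition is None:
        condition = ConditionSpec(mode="paired" if len(timelines) == 2 else "solitary")

    counts = []
    for timeline in timelines:
        k_total = 0
        for zone, dwell in timeline:
            if zone not in ("A", "B", "C"):
                raise ValueError(f"unknown zone label {zone!r}")
            k = dwell / dt_s
            if dwell <= 0 or abs(k - round(k)) > 1e-6:
                raise ValueError(
                    f"dwell {dwell} s is not a positive multiple of dt={dt_s} s"
                )
            k_total += int(round(k))
        counts.append(k_total)
    if len(set(counts)) != 1:
        raise ValueError(
            f"subjects must share one total duration; got {counts} samples"
        )

    frames = []
    for i, timeline in enumerate(timelines):
        xs: list[np.ndarray] = []
        for zone, dwell in timeline:
            k = int(round(dwell / dt_s))
            xs.append(np.full(k, geom.zone_center_cm(zone)))
        x = np.concatenate(xs)
        y = np.full_like(x, geom.lane_center_cm(min(i, geom.n_lanes - 1)))
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.arange(len(x)) * dt_s,
                    "subject_id": f"rat{i + 1}",
                    "x_cm": x,
                    "y_cm": y,
                }
            )
        )
    tracks = SessionTracks(
        data=pd.concat(frames, ignore_index=True),
        condition=condition,
        dt_s=dt_s,
        **meta,
    )
    tracks.validate()
    return tracks
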
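"""Maze coordinate system, zone partition, and rule constants.

The apparatus is a two-lane linear maze (default 120 cm long, 40 cm wide)
whose long axis is partitioned into three virtual zones:

* ``A`` — the start zone at the near wall,
* ``B`` — the middle zone,
* ``C`` — the reward zone at the far wall, where the liquid dispensers sit.

Zone membership depends only on the longitudinal coordinate ``x``; the two
lanes share the same partition because the divider runs along the maze axis.
Everything downstream (the trial engine, the metrics, the simulator) speaks
in these zone labels, so this module is the single authority for how a
coordinate maps to a zone and for the rule constants of a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ZONES",
    "DIVIDERS",
    "MazeGeometry",
    "EngineParams",
    "ConditionSpec",
    "OutOfMazeError",
    "zone_of",
    "zones_of",
    "zone_sequence",
    "zone_distance",
]

#: Ordered zone labels from the start wall to the reward wall.
ZONES: tuple[str, str, str] = ("A", "B", "C")

_ZONE_INDEX = {z: i for i, z in enumerate(ZONES)}

#: The four divider builds between the two lanes, ordered as introduced in
#: the apparatus description (sealed blocks everything; perforated passes
#: sound/smell; transparent passes vision; transparent_perforated passes all
#: non-physical modalities).
DIVIDERS: tuple[str, ...] = (
    "sealed",
    "perforated",
    "transparent",
    "transparent_perforated",
)

_MODES = ("paired", "solitary")
_SEXES = ("female", "male", "unspecified")


class OutOfMazeError(ValueError):
    """A longitudinal coordinate fell outside ``[0, length_cm]``."""


@dataclass(frozen=True)
class MazeGeometry:
    """Physical extent of the maze and the zone partition of its long axis.

    Parameters
    ----------
    length_cm
        Longitudinal extent (start wall to reward wall).
    width_cm
        Transverse extent across both lanes.
    n_lanes
        Number of parallel lanes (one subject each).
    zone_bounds_cm
        Two ascending interior boundaries splitting ``[0, length_cm]`` into
        zones A, B, C.  Defaults to equal thirds; the apparatus description
        fixes only that three zones span the maze, so the split is
        configurable.
    hysteresis_cm
        Optional dead-band half-width applied by :func:`zone_sequence` so
        tracker jitter on a boundary does not flicker between zones.  The
        default 0 disables it.
    """

    length_cm: float = 120.0
    width_cm: float = 40.0
    n_lanes: int = 2
    zone_bounds_cm: tuple[float, float] = (40.0, 80.0)
    hysteresis_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("maze extents must be strictly positive")
        if self.n_lanes < 1:
            raise ValueError("n_lanes must be >= 1")
        b1, b2 = self.zone_bounds_cm
        if not (0.0 < b1 < b2 < self.length_cm):
            raise ValueError(
                f"zone bounds must satisfy 0 < {b1} < {b2} < {self.length_cm}"
            )
        if self.hysteresis_cm < 0:
            raise ValueError("hysteresis_cm must be >= 0")

    def zone_center_cm(self, zone: str) -> float:
        """Longitudinal midpoint of a zone (used to synthesize fixtures)."""
        b1, b2 = self.zone_bounds_cm
        edges = {"A": (0.0, b1), "B": (b1, b2), "C": (b2, self.length_cm)}
        try:
            lo, hi = edges[zone]
        except KeyError:
            raise ValueError(f"unknown zone label {zone!r}") from None
        return 0.5 * (lo + hi)

    def lane_center_cm(self, lane: int) -> float:
        """Lateral midpoint of lane ``lane`` (0-based)."""
        if not 0 <= lane < self.n_lanes:
            raise ValueError(f"lane {lane} out of range for {self.n_lanes} lanes")
        lane_w = self.width_cm / self.n_lanes
        return (lane + 0.5) * lane_w


@dataclass(frozen=True)
class EngineParams:
    """Rule constants of one scored session.

    ``max_mismatch_s`` is the continuous different-zone tolerance: the pair
    fails the current trial once they have been in different zones for
    strictly more than this many seconds.  A session ends at
    ``max_rewarded_trials`` successes or ``max_session_s`` elapsed time,
    whichever comes first.  ``reward_volume_ul``/``pump_duration_s`` are
    echoed into every reward event (70 µl of 20 % sucrose over 1.5 s pump
    activation under defaults).
    """

    max_mismatch_s: float = 10.0
    max_rewarded_trials: int = 20
    max_session_s: float = 900.0
    reward_volume_ul: float = 70.0
    pump_duration_s: float = 1.5
    mode: str = "paired"

    def __post_init__(self) -> None:
        for name in (
            "max_mismatch_s",
            "max_rewarded_trials",
            "max_session_s",
            "reward_volume_ul",
            "pump_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_session_s < self.max_mismatch_s:
            raise ValueError("max_session_s must be >= max_mismatch_s")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def n_subjects(self) -> int:
        return 2 if self.mode == "paired" else 1


@dataclass(frozen=True)
class ConditionSpec:
    """Experimental condition of a session.

    ``divider`` names the partition between the lanes and controls which
    sensory modalities connect the partners; ``context_cues`` marks the
    arm with extra visual patterns on the maze walls; ``sex`` labels the
    pair; ``mode`` distinguishes cooperating pairs from solitary runs.
    """

    divider: str = "transparent_perforated"
    context_cues: bool = False
    sex: str = "unspecified"
    mode: str = "paired"

    def __post_init__(self) -> None:
        if self.divider not in DIVIDERS:
            raise ValueError(
                f"divider must be one of {DIVIDERS}, got {self.divider!r}"
            )
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def n_subjects(self) -> int:
        return 2 if self.mode == "paired" else 1

    def label(self) -> str:
        """Compact string used as the grouping key in metric tables."""
        parts = [self.mode, self.divider]
        if self.context_cues:
            parts.append("context")
        if self.sex != "unspecified":
            parts.append(self.sex)
        return "+".join(parts)


def zone_of(x_cm: float, geom: MazeGeometry | None = None) -> str:
    """Map a longitudinal coordinate to its zone label.

    The partition is half-open and lower-inclusive — a sample exactly on a
    boundary belongs to the farther zone — with zone C closed at the far
    wall, so ``x == length_cm`` is still inside the maze.

    Raises
    ------
    OutOfMazeError
        If ``x_cm`` falls outside ``[0, length_cm]``.
    """
    geom = geom or MazeGeometry()
    if not np.isfinite(x_cm) or x_cm < 0 or x_cm > geom.length_cm:
        raise OutOfMazeError(
            f"x={x_cm!r} cm outside maze [0, {geom.length_cm}] cm"
        )
    b1, b2 = geom.zone_bounds_cm
    if x_cm < b1:
        return "A"
    if x_cm < b2:
        return "B"
    return "C"


def zones_of(x_cm: Sequence[float] | np.ndarray, geom: MazeGeometry | None = None) -> np.ndarray:
    """Vectorized :func:`zone_of` over an array of coordinates."""
    geom = geom or MazeGeometry()
    x = np.asarray(x_cm, dtype=float)
    bad = ~np.isfinite(x) | (x < 0) | (x > geom.length_cm)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise OutOfMazeError(
            f"sample {i}: x={x.flat[i]!r} cm outside maze [0, {geom.length_cm}] cm"
        )
    b1, b2 = geom.zone_bounds_cm
    idx = (x >= b1).astype(np.int8) + (x >= b2).astype(np.int8)
    return np.array(ZONES, dtype="<U1")[idx]


def zone_sequence(x_cm: Sequence[float] | np.ndarray, geom: MazeGeometry | None = None) -> np.ndarray:
    """Zone labels along a track, optionally with boundary hysteresis.

    With ``geom.hysteresis_cm == 0`` this is exactly :func:`zones_of`.
    With a positive dead-band, the zone only changes once the coordinate
    has moved ``hysteresis_cm`` past a boundary, which suppresses tracker
    jitter oscillating across it.
    """
    geom = geom or MazeGeometry()
    if geom.hysteresis_cm == 0.0:
        return zones_of(x_cm, geom)
    x = np.asarray(x_cm, dtype=float)
    plain = zones_of(x, geom)  # validates range
    h = geom.hysteresis_cm
    b1, b2 = geom.zone_bounds_cm
    out = np.empty(len(x), dtype="<U1")
    cur = plain[0]
    out[0] = cur
    for i in range(1, len(x)):
        xi = x[i]
        ci = _ZONE_INDEX[cur]
        # advance only when clearly past the boundary on the far side
        if ci < 2 and xi >= (b1, b2)[ci] + h:
            cur = ZONES[ci + 1]
            ci += 1
        if ci > 0 and xi < (b1, b2)[ci - 1] - h:
            cur = ZONES[ci - 1]
        out[i] = cur
    return out


def zone_distance(z1: str, z2: str) -> int:
    """Ordinal distance between two zone labels (A=0, B=1, C=2).

    A distance of 2 — one subject in A while the other is in C — is the
    configuration that instantly fails a trial.
    """
    try:
        return abs(_ZONE_INDEX[z1] - _ZONE_INDEX[z2])
    except KeyError as e:
        raise ValueError(f"unknown zone label {e.args[0]!r}") from None
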
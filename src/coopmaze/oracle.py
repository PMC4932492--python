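"""Naive full-scan re-scoring of a session, used only as a test oracle.

This walks the raw per-sample zone sequences with plain index scans and
window re-inspection — no incremental engine state — and recomputes the
arm/restart instants, different-zone stretches, progression orders and
outcomes directly from the arrays.  It exists so the trial engine can be
checked against an implementation with a different shape.
"""

from __future__ import annotations

import numpy as np

from .maze_model import EngineParams, MazeGeometry, zone_sequence
from .track_io import SessionTracks

__all__ = ["score_session_oracle"]

_EPS = 1e-9


def score_session_oracle(
    tracks: SessionTracks,
    params: EngineParams | None = None,
    geom: MazeGeometry | None = None,
) -> tuple[int, int]:
    """Return ``(reward_count, break_count)`` for a session.

    Same rules and precedence as the engine, recomputed by scanning.
    """
    params = params or EngineParams(mode=tracks.condition.mode)
    geom = geom or MazeGeometry()
    subjects = tracks.subjects
    if len(subjects) != params.n_subjects:
        raise ValueError("subject count does not match params.mode")
    zs = [zone_sequence(tracks.subject(s)["x_cm"].to_numpy(), geom) for s in subjects]
    t = tracks.subject(subjects[0])["time_s"].to_numpy()
    n = len(t)
    paired = len(zs) == 2

    # index at which the session clock expires; nothing at or past it counts
    over = np.flatnonzero(t >= params.max_session_s - _EPS)
    limit = int(over[0]) if over.size else n

    def everyone_in(i: int, zone: str) -> bool:
        return all(z[i] == zone for z in zs)

    rewards = 0
    breaks = 0

    # find the first arming instant
    i = 0
    while i < limit and not everyone_in(i, "A"):
        i += 1
    if i >= limit:
        return 0, 0

    armed_at = i
    while True:
        # scan for the sample where some subject leaves A
        j = armed_at + 1
        while j < limit and everyone_in(j, "A"):
            j += 1
        if j >= limit:
            return rewards, breaks  # armed (not active) when the clock ran out

        # trial active over samples j, j+1, ...
        diff_run_start = -1          # start index of the current different-zone run
        first_c = [-1] * len(zs)     # first C-entry index per subject, -1 if none
        outcome_at = -1
        for k in range(j, limit):
            if everyone_in(k, "A"):
                armed_at = k         # restart in place
                break
            for s in range(len(zs)):
                if zs[s][k] == "C" and first_c[s] < 0:
                    first_c[s] = k
            if paired:
                za, zb = zs[0][k], zs[1][k]
                if {za, zb} == {"A", "C"}:
                    breaks += 1
                    outcome_at = k
                    break
                if za != zb:
                    if diff_run_start < 0:
                        diff_run_start = k
                    run_t = t[k] - t[diff_run_start - 1] if diff_run_start > 0 else t[k]
                    if run_t > params.max_mismatch_s + _EPS:
                        breaks += 1
                        outcome_at = k
                        break
                else:
                    diff_run_start = -1
            if everyone_in(k, "C"):
                # valid only if every subject's first C entry was preceded,
                # within this trial, by a B dwell that followed the A start
                ok = True
                for s in range(len(zs)):
                    fc = first_c[s]
                    window = zs[s][j:fc]  # samples strictly before first C entry
                    if "B" not in window:
                        ok = False
                        break
                if ok:
                    rewards += 1
                    outcome_at = k
                    if rewards >= params.max_rewarded_trials:
                        return rewards, breaks
                    break
        else:
            # clock (or track) ran out mid-trial
            breaks += 1
            return rewards, breaks

        if outcome_at < 0:
            continue  # restarted; armed_at already updated

        # after an outcome: wait for both subjects back in A
        m = outcome_at + 1
        while m < limit and not everyone_in(m, "A"):
            m += 1
        if m >= limit:
            return rewards, breaks
        armed_at = m
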
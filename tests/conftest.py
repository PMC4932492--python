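import numpy as np
import pytest

from coopmaze import fixture_from_zone_timeline

ZONES = ("A", "B", "C")


def circuit_timeline(n_circuits, a_s=5.0, b_s=5.0, c_s=10.0, back_a_s=5.0):
    """Timeline of n synchronized A→B→C→A circuits."""
    tl = []
    for _ in range(n_circuits):
        tl.extend([("A", a_s), ("B", b_s), ("C", c_s), ("A", back_a_s)])
    return tl


def random_timeline_tracks(rng, dt_s=0.1, min_segments=3, max_segments=25,
                           min_dwell_s=0.5, max_dwell_s=30.0):
    """Two-subject tracks with random zone orders and dwell times.

    Dwells are exact multiples of dt; the shorter subject is padded with a
    final random-zone dwell so both cover the same duration.
    """
    timelines = []
    nseg = int(rng.integers(min_segments, max_segments + 1))
    lo, hi = int(round(min_dwell_s / dt_s)), int(round(max_dwell_s / dt_s))
    for _ in range(2):
        tl = [
            (ZONES[int(rng.integers(3))], int(rng.integers(lo, hi + 1)) * dt_s)
            for _ in range(nseg)
        ]
        timelines.append(tl)
    totals = [round(sum(d for _, d in tl) / dt_s) for tl in timelines]
    m = max(totals)
    for tl, tot in zip(timelines, totals):
        if tot < m:
            tl.append((ZONES[int(rng.integers(3))], (m - tot) * dt_s))
    return fixture_from_zone_timeline(timelines, dt_s=dt_s)


@pytest.fixture
def glued_pair_30_circuits():
    """Identical tracks doing 30 synchronized 25 s circuits (750 s total)."""
    tl = circuit_timeline(30)
    return fixture_from_zone_timeline([tl, tl], dt_s=0.1)


def trailing_pair_tracks(lag_s, dt_s=0.1):
    """Subject 2 trails subject 1 into each zone by ``lag_s`` seconds."""
    lead = [("A", 5.0), ("B", 15.0), ("C", 30.0)]
    trail = [("A", 5.0 + lag_s), ("B", 15.0), ("C", 30.0 - lag_s)]
    return fixture_from_zone_timeline([lead, trail], dt_s=dt_s)
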
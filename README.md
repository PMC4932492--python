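# coopmaze

Automated scoring and simulation for a two-lane rodent **social-cooperation
maze** — a fully automated, non-conditioned assay in which two rats earn a
mutual sucrose reward by shuttling *coordinately* down a 120 cm corridor.

The package is for behavioral researchers who have (or want to prototype
against) tracker output from such an apparatus: it replays time-stamped
position tracks through the maze's cooperation algorithm, emits the reward
and failure events a live rig would produce, computes the standard
behavioral measures and learning curves, and ships a coupled
stochastic-agent simulator so every rule and metric can be exercised
end-to-end without hardware or animals.

## The cooperation algorithm

The maze (40 cm W × 120 cm L, two lanes separated by a divider) is
partitioned along its long axis into three virtual zones *A* (start), *B*
(middle) and *C* (reward). With per-subject zone occupancy z₁(t), z₂(t)
sampled on a uniform grid, a session is scored by a trial state machine:

- **Arm** — a trial arms when both subjects occupy zone A, and (re)starts
  whenever both return to A.
- **Success** — a trial is rewarded when both subjects are simultaneously
  in C, each having progressed A → B → C within the trial. A reward event
  carries the pump parameters (default 70 µl of 20 % sucrose per rat, 1.5 s
  pump activation).
- **Failure** — an active trial breaks the instant the subjects are more
  than one zone apart (A and C), or once they have occupied *different*
  zones for strictly more than 10 continuous seconds (the different-zone
  timer resets on reunion; exactly 10 s still passes).
- **Session end** — after 20 rewarded trials or 15 minutes, whichever
  comes first.

A solitary mode degenerates every pair rule to the single subject's own
A → B → C traversal. Per-session measures are the reward count R, the
**activity** D (total path length of the pair, cm), the **efficacy index**
R·D⁻¹ (rewards per cm — the utility of the cooperation), and the
**latency** to the pair's first joint arrival in C; sessions aggregate into
per-day mean ± SEM learning curves across pairs.

## Worked example

Score a hand-built session in which subject 2 trails subject 1 into every
zone by 9 s (inside the 10 s tolerance):

```python
from coopmaze import fixture_from_zone_timeline, run_session, session_metrics

lead  = [("A", 5.0),  ("B", 15.0), ("C", 30.0)]
trail = [("A", 14.0), ("B", 15.0), ("C", 21.0)]   # 9 s behind
tracks = fixture_from_zone_timeline([lead, trail], dt_s=0.1)

result = run_session(tracks)
for ev in result.events:
    print(f"t={ev.t_s:6.1f}s  {ev.kind:12s} zones={ev.zones}")
row = session_metrics(result, tracks)
print(row.rewards, round(row.activity_cm, 1), row.efficacy, row.latency_s)
```

```
t=   0.0s  trial_armed  zones=('A', 'A')
t=  29.0s  reward       zones=('C', 'C')
t=  49.9s  session_end  zones=('C', 'C')
1 160.0 0.00625 29.0
```

One trial arms at t = 0; the pair completes a coordinated A→B→C run, and
the reward fires at t = 29.0 s, the moment the trailing subject joins its
partner in zone C (which is also the pair's latency). The pair covered
160 cm, giving an efficacy of 1/160 = 0.00625 rewards·cm⁻¹. Raise the lag
to 11 s and the same session ends in a `mismatch_timeout` break instead.

The same run from the shell:

```bash
coopmaze score --tracks session.csv --out-events events.csv --out-metrics metrics.csv
coopmaze simulate --demo --seed 0 --out-dir demo/   # 11 pairs, 18+6 days
coopmaze aggregate --metrics metrics.csv --out curves.csv
```

`simulate --demo` runs the full simulated protocol — 18 acquisition days
followed by a partner swap and 6 more days, 11 pairs — and writes
per-session metrics plus per-day learning-curve tables showing the rising
reward/efficacy curves, the day-19 dip above naive performance (latent
learning), and the falling latency.

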
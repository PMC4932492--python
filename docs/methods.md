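# Methods

## Scope and data model

`coopmaze` scores *already-tracked* coordinates: plain-text long-format
tables of `time_s, subject_id, x_cm, y_cm`, one row per video frame per
subject. It does not decode video, estimate pose, or talk to hardware.
Tracks are linearly interpolated onto one shared uniform grid (default
0.04 s ≈ 25 Hz, a common camera frame rate) from 0 to the earliest
per-subject last timestamp; gaps longer than 1 s are flagged as warnings
but still interpolated, because the scoring rules have no missing-data
concept. Only the longitudinal coordinate `x` enters scoring; `y` and the
lane identity are carried through I/O and used for path length.

## Zone partition

The 120 cm axis is split at 40 cm and 80 cm into zones A, B, C. The
apparatus description fixes only that three zones span the maze, so the
boundaries are configuration, defaulting to equal thirds. The convention
is half-open and lower-inclusive (a sample exactly on a boundary belongs
to the farther zone; C is closed at the far wall), which makes "arrival"
at a zone unambiguous. An optional hysteresis dead-band (default 0 cm)
suppresses tracker jitter oscillating across a boundary; it is off by
default so that scored zone sequences equal the raw assignment.

## Trial state machine

Phases: *pre-armed* (waiting for the first simultaneous A occupancy —
subjects are assumed to start in A; if not, no trial can complete before
both are first seen there), *armed*, *active*, *broken* (after an
outcome, coordination rules suspended — the animals must drink and walk
back), *done* (absorbing). Decisions taken where the rules were open:

- **"20 successive trials"** is implemented as 20 *rewarded* trials: in
  free-running behavior failed coordination is continuous, not discretely
  counted. The cap is configurable.
- **The 10 s rule** is one continuous different-zone timer that resets on
  reunion, with a strict inequality: accumulated different-zone time of
  exactly 10 s still rewards, anything longer breaks. Comparisons carry a
  1 ns tolerance so binary-float accumulation cannot flip the boundary
  case either way.
- **Progression** requires each subject's *first* C entry in a trial to
  have been preceded (within the trial) by a B dwell. Backtracking (e.g.
  B→A→B by one subject) does not reset progression, because a trial only
  restarts when *both* subjects return to A; when that happens the trial
  re-arms in place and no outcome is recorded for the abandoned attempt.
- **"Together at C"** means simultaneously in zone C at a grid sample; no
  extra togetherness window is added since the inter-subject arrival gap
  is already bounded by the mismatch timer.
- **Precedence** at one sample is fixed: session caps, then the
  two-zones-apart break, then the mismatch timeout, then the reward.

A trial open when the clock or the recording ends is closed as a break
with cause `session_end`. In solitary mode the pair rules degenerate to
the single subject (success = own A→B→C, re-arm = own return to A; the
mismatch and two-apart rules cannot fire).

An independent brute-force scorer (`coopmaze.oracle`) re-derives reward
and break counts by naive scanning of the zone arrays, with no shared
engine state; the test suite holds the two implementations equal over
thousands of randomized sessions.

## Behavioral measures

Activity is total path length (cm) over the *scored* duration, summed
over the pair (the per-subject split is retained); the efficacy index is
rewards per cm with efficacy = 0 when activity = 0; latency is the time
of the first simultaneous pair occupancy of C whether or not it earned a
reward (a flag switches to first-reward latency), reported as missing —
never imputed — when the pair never gets there. Aggregation over pairs
uses mean and SEM (sample SD/√n; 0 for n = 1), with censored latencies
excluded and the latency n adjusted per cell. Percent change against a
baseline day is computed on per-day means as 100·(baseline − value)/baseline
with delta-method SEM propagation.

## Simulator

The simulator exists to generate *realistic, controllable* sessions whose
scored phenomenology matches the qualitative published patterns — a
progressive learning curve, a partner-swap dip above naive performance,
divider-graded performance, contextual-cue impairment with unchanged
activity, a solitary advantage, and a speed-mediated sex contrast — not
to fit any empirical curve.

Each agent is one-dimensional along the maze axis and cycles through four
states: *deciding* (pacing inside zone A), *run to C*, *drinking* (a
fixed dwell at the reward wall, default 8 s), *return to A*. Runs follow
an Euler–Maruyama update `dx = (goal drift + partner pull) dt + noise`,
where the drift is `goal_gain × speed` toward the current wall, the pull
is `coupling_eff × speed × tanh(Δx/30 cm)` (bounded, so a distant partner
cannot fling the agent), and the noise scale is `noise_sd √dt`. Positions
clip to the maze.

A deciding agent commits to a run at exponentially spaced decision times
(mean 8 s) with probability `0.05 + 0.95 × coupling_eff` — initiation is
social attention — and commits implicitly if the partner's pull drags it
out of zone A. A solitary agent's commitment uses its own task skill
(`goal_gain`) instead, which is why solitary subjects out-earn pairs: no
partner to wait for and no coordination rules to fail. An earlier design
without the commitment layer was discarded: with pure drift + attraction
dynamics, even weak coupling phase-locks the pair, and once agents are
fast the 10 s rule can essentially never fire, so coupling (and hence the
divider, context and swap manipulations) stopped mattering.

**Learning** is exponential saturation per individual:
`p(e) = p∞ − (p∞ − p₀)e^(−λe)` over that individual's days of training
`e`, applied to `goal_gain` (task skill, default 0.12 → 0.85, λ = 0.13)
and `coupling` (social skill, default 0.10 → 0.95, λ = 0.18). The
effective coupling is
`coupling(e) × familiarity × divider × (1 − context penalty)`:

- **familiarity** grows with days spent with the *current* partner
  (floor 0.5, rate 0.6/day) and restarts at a partner swap. Individual
  skill persists across the swap, so day 19 dips yet stays far above
  day 1 and recovers within days — latent learning as an emergent
  consequence, not a hard-coded day effect.
- **divider** multipliers (all-modality 1.0, transparent 0.7, sealed 0.4,
  perforated 0.35) encode only the published performance *ordering*,
  never measured effect sizes; they are configuration values.
- **context** cues are modeled as an attention penalty on coupling
  (default 0.35), not on speed, which reproduces "fewer rewards,
  unchanged activity".

The sex contrast rescales speed *and* noise jointly (default female ×1.25),
so rewards and activity rise together while path efficiency — and hence
the efficacy index — is approximately preserved. Default kinematics:
speed 14 cm/s, noise 3 cm/√s, dt 0.1 s, 900 s sessions. Mild
per-individual heterogeneity (lognormal multipliers, σ = 0.08, on speed
and learning rates) keeps pairs from being clones. All randomness derives
from one master seed through per-arm/pair/day `SeedSequence` substreams,
so any single session reproduces in isolation.

### What the simulator does and does not emulate

It emulates tracker output statistically: plausible speeds, pauses,
within-zone pacing, boundary-crossing variability, and condition effects
expressed through a single coupling channel. It does not emulate real
tracker artifacts (identity swaps, dropouts, lens distortion), grooming
or rearing, satiety within a session, or any biophysical model of rodent
gait — so green simulator-based tests demonstrate that the *scoring and
aggregation pipeline* behaves correctly under realistic input statistics,
not that real rats behave like the agents.

## Problem sizes and numerical choices

The end-to-end checks run the headline protocol at study scale (11 pairs,
18 + 6 days, swap on day 19), condition arms at 5 pairs × 18 days, the
engine–oracle equivalence on 1,000 randomized zone-timeline sessions, and
the coupling trend on a 5-point grid × 50 seeds — sizes chosen so the
whole suite completes in a couple of minutes on one core while keeping
per-cell SEMs well below the asserted contrasts. Zone-timeline fixtures
require dwells to be exact multiples of the grid step so constructed zone
sequences are bit-exact; session-clock and mismatch comparisons use a
1 ns slack; ties at one grid sample resolve in the fixed precedence order
listed above.

## Known limitations

- Zone boundary positions are a configuration default (equal thirds), not
  an apparatus fact.
- Whether the original rig counted attempts or successes toward the
  20-trial cap, and whether it forbade backtracking, is not derivable
  from the published description; both choices here are documented
  defaults.
- The efficacy index inherits the sampling-rate sensitivity of raw path
  length (jitter inflates distance); compare efficacies only across
  sessions resampled at the same rate.
- Simulator parameters are design values that realize directions and
  orderings of published effects; magnitudes are not calibrated to data.
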
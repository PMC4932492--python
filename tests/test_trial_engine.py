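import numpy as np
import pytest

from conftest import circuit_timeline, random_timeline_tracks, trailing_pair_tracks

from coopmaze.maze_model import EngineParams
from coopmaze.oracle import score_session_oracle
from coopmaze.track_io import fixture_from_zone_timeline
from coopmaze.trial_engine import EngineError, EngineState, run_session, step


class TestStep:
    def test_two_zones_apart_breaks_instantly(self):
        lead = [("A", 5.0), ("B", 5.0), ("C", 20.0)]
        lag = [("A", 25.0), ("B", 5.0)]
        res = run_session(fixture_from_zone_timeline([lead, lag], dt_s=0.1))
        assert res.n_rewards == 0
        assert [t.cause for t in res.trials if t.outcome == "break"] == ["two_zones_apart"]
        # the break happens the moment the leader enters C with the partner in A
        brk = res.events.of_kind("break")[0]
        assert brk.t_s == pytest.approx(10.0, abs=0.2)
        assert set(brk.zones) == {"A", "C"}

    def test_mismatch_strictly_greater_than_window(self):
        """Different zones for exactly 10 s passes; any longer fails."""
        params = EngineParams()
        for lag, rewarded in [(9.0, True), (10.0, True), (11.0, False)]:
            res = run_session(trailing_pair_tracks(lag), params)
            assert (res.n_rewards == 1) is rewarded, f"lag={lag}"
            if not rewarded:
                assert res.trials[0].cause == "mismatch_timeout"

    def test_reward_requires_full_progression(self):
        # subject 2 jumps A→C without a B dwell: no reward even when both in C
        s1 = [("A", 5.0), ("B", 5.0), ("C", 20.0)]
        s2 = [("A", 9.0), ("C", 21.0)]
        res = run_session(fixture_from_zone_timeline([s1, s2], dt_s=0.1))
        assert res.n_rewards == 0

    def test_backtracking_does_not_reset_progression(self):
        # B→A→B wandering before C still rewards (restart needs BOTH in A)
        s1 = [("A", 2.0), ("B", 8.0), ("C", 6.0)]
        s2 = [("A", 4.0), ("B", 2.0), ("A", 2.0), ("B", 2.0), ("C", 6.0)]
        res = run_session(fixture_from_zone_timeline([s1, s2], dt_s=0.1))
        assert res.n_rewards == 1

    def test_step_rejects_done_phase_and_bad_labels(self):
        state = EngineState(params=EngineParams())
        with pytest.raises(EngineError, match="invalid zone"):
            step(state, ("A", "D"), 0.0, 0.1)
        state.phase = "done"
        with pytest.raises(EngineError, match="ended"):
            step(state, ("A", "A"), 0.0, 0.1)


class TestRunSession:
    def test_trial_cap_binds_on_glued_pair(self, glued_pair_30_circuits):
        res = run_session(glued_pair_30_circuits)
        assert res.n_rewards == 20
        assert res.events.events[-1].kind == "session_end"
        assert res.scored_duration_s < 750.0

    def test_time_cap_truncates_scored_duration(self):
        tl = []
        for _ in range(15):
            tl.extend(circuit_timeline(1, 20.0, 30.0, 40.0, 30.0))
        res = run_session(fixture_from_zone_timeline([tl, tl], dt_s=0.1))
        assert res.scored_duration_s == pytest.approx(900.0, abs=1e-9)
        assert res.n_rewards < 20

    def test_stationary_pair_never_rewards(self):
        tl = [("A", 910.0)]
        res = run_session(fixture_from_zone_timeline([tl, tl], dt_s=0.1))
        assert (res.n_rewards, res.n_breaks) == (0, 0)
        assert res.scored_duration_s == pytest.approx(900.0)

    def test_never_shared_zone_yields_zero_rewards(self):
        s1 = [("A", 10.0), ("B", 10.0), ("A", 10.0), ("B", 10.0)]
        s2 = [("B", 10.0), ("C", 10.0), ("B", 10.0), ("C", 10.0)]
        res = run_session(fixture_from_zone_timeline([s1, s2], dt_s=0.1))
        assert res.n_rewards == 0

    def test_solitary_circuits_reward_once_each(self):
        n = 7
        tl = circuit_timeline(n)
        res = run_session(
            fixture_from_zone_timeline([tl], dt_s=0.1),
            EngineParams(mode="solitary"),
        )
        assert res.n_rewards == n

    def test_no_events_after_session_end(self, glued_pair_30_circuits):
        res = run_session(glued_pair_30_circuits)
        kinds = [e.kind for e in res.events]
        assert kinds.index("session_end") == len(kinds) - 1

    def test_reward_events_carry_pump_parameters(self):
        tl = circuit_timeline(1)
        res = run_session(fixture_from_zone_timeline([tl, tl], dt_s=0.1))
        rw = res.events.of_kind("reward")[0]
        assert (rw.reward_volume_ul, rw.pump_duration_s) == (70.0, 1.5)

    def test_tightening_mismatch_window_never_adds_rewards(self):
        rng = np.random.default_rng(42)
        fixtures = [random_timeline_tracks(rng) for _ in range(8)]
        for tracks in fixtures:
            counts = [
                run_session(tracks, EngineParams(max_mismatch_s=w)).n_rewards
                for w in (20.0, 10.0, 5.0, 2.0, 0.5)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:])), counts

    def test_unsynchronized_grids_rejected(self):
        import pandas as pd

        from coopmaze.maze_model import ConditionSpec
        from coopmaze.track_io import SessionTracks
        df = pd.concat(
            [
                pd.DataFrame({"time_s": [0.0, 1.0], "subject_id": "r1", "x_cm": 0.0, "y_cm": 10.0}),
                pd.DataFrame({"time_s": [0.0, 1.5], "subject_id": "r2", "x_cm": 0.0, "y_cm": 30.0}),
            ],
            ignore_index=True,
        )
        with pytest.raises(EngineError, match="resample"):
            run_session(SessionTracks(data=df, condition=ConditionSpec()))

    def test_subject_count_must_match_mode(self):
        tl = [("A", 1.0)]
        tracks = fixture_from_zone_timeline([tl], dt_s=0.1)
        with pytest.raises(EngineError, match="paired"):
            run_session(tracks, EngineParams(mode="paired"))


class TestOracleAgreement:
    def test_glued_pair_fixture(self, glued_pair_30_circuits):
        res = run_session(glued_pair_30_circuits)
        assert score_session_oracle(glued_pair_30_circuits) == (res.n_rewards, res.n_breaks)

    def test_empty_movement_session(self):
        tracks = fixture_from_zone_timeline([[("B", 30.0)], [("B", 30.0)]], dt_s=0.1)
        assert score_session_oracle(tracks) == (0, 0)

    def test_randomized_sessions_agree(self):
        """Engine and brute-force oracle agree on reward AND break counts."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            tracks = random_timeline_tracks(rng)
            res = run_session(tracks)
            assert score_session_oracle(tracks) == (res.n_rewards, res.n_breaks)

    def test_solitary_sessions_agree(self):
        rng = np.random.default_rng(7)
        params = EngineParams(mode="solitary")
        for _ in range(60):
            nseg = int(rng.integers(3, 20))
            tl = [("ABC"[int(rng.integers(3))], int(rng.integers(5, 300)) * 0.1)
                  for _ in range(nseg)]
            tracks = fixture_from_zone_timeline([tl], dt_s=0.1)
            res = run_session(tracks, params)
            assert score_session_oracle(tracks, params) == (res.n_rewards, res.n_breaks)
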
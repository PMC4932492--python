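import numpy as np
import pandas as pd
import pytest

from coopmaze.maze_model import ConditionSpec, MazeGeometry, zones_of
from coopmaze.track_io import (
    Event,
    EventLog,
    TrackValidationError,
    fixture_from_zone_timeline,
    read_events,
    read_events_jsonl,
    read_tracks,
    resample,
    write_events,
    write_events_jsonl,
    write_tracks,
)


def _write_csv(path, rows, header="time_s,subject_id,x_cm,y_cm"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadTracks:
    def test_two_subject_file(self, tmp_path):
        rows = [f"{t/10},r1,{t},10" for t in range(10)]
        rows += [f"{t/10},r2,{t},30" for t in range(10)]
        f = tmp_path / "t.csv"
        _write_csv(f, rows)
        tracks = read_tracks(f, ConditionSpec())
        assert tracks.subjects == ["r1", "r2"]
        assert len(tracks.subject("r1")) == 10

    def test_three_subjects_rejected(self, tmp_path):
        rows = [f"0.0,r{i},0,0\n1.0,r{i},1,0".replace("\n", "\n") for i in (1, 2, 3)]
        f = tmp_path / "t.csv"
        _write_csv(f, [r for block in rows for r in block.split("\n")])
        with pytest.raises(TrackValidationError, match="at most 2"):
            read_tracks(f, ConditionSpec())

    def test_negative_timestamp_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["-1.0,r1,0,0", "0.0,r1,1,0", "0.0,r2,0,0", "1.0,r2,1,0"])
        with pytest.raises(TrackValidationError, match="negative timestamp"):
            read_tracks(f, ConditionSpec())

    def test_non_monotone_timestamps_name_the_line(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["0.0,r1,0,0", "1.0,r1,1,0", "1.0,r1,2,0",
                       "0.0,r2,0,0", "1.0,r2,1,0", "2.0,r2,2,0"])
        with pytest.raises(TrackValidationError, match="line 4"):
            read_tracks(f, ConditionSpec())

    def test_missing_columns(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["0.0,r1,0"], header="time_s,subject_id,x_cm")
        with pytest.raises(TrackValidationError, match="missing columns"):
            read_tracks(f, ConditionSpec())

    def test_mode_subject_count_mismatch(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["0.0,r1,0,0", "1.0,r1,1,0"])
        with pytest.raises(TrackValidationError, match="paired"):
            read_tracks(f, ConditionSpec(mode="paired"))
        assert read_tracks(f, ConditionSpec(mode="solitary")).n_subjects == 1

    def test_column_mapping(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["0.0,r1,5,1", "1.0,r1,6,1"], header="t,animal,posx,posy")
        tracks = read_tracks(
            f, ConditionSpec(mode="solitary"),
            column_map={"time_s": "t", "subject_id": "animal", "x_cm": "posx", "y_cm": "posy"},
        )
        assert tracks.subject("r1")["x_cm"].tolist() == [5.0, 6.0]

    def test_write_read_round_trip(self, tmp_path):
        tl = [("A", 2.0), ("B", 1.0)]
        tracks = fixture_from_zone_timeline([tl, tl], dt_s=0.5)
        f = tmp_path / "rt.csv"
        write_tracks(tracks, f)
        back = read_tracks(f, tracks.condition)
        pd.testing.assert_frame_equal(
            back.data, tracks.data[list(back.data.columns)], check_dtype=False
        )


class TestResample:
    def _tracks(self, t, x, mode="solitary"):
        df = pd.DataFrame({"time_s": t, "subject_id": "r1", "x_cm": x, "y_cm": 10.0})
        from coopmaze.track_io import SessionTracks
        return SessionTracks(data=df, condition=ConditionSpec(mode=mode))

    def test_linearity(self):
        tr = self._tracks([0.0, 10.0], [0.0, 120.0])
        out = resample(tr, 5.0)
        sub = out.subject("r1")
        assert sub["time_s"].tolist() == [0.0, 5.0, 10.0]
        assert sub["x_cm"].tolist() == [0.0, 60.0, 120.0]

    def test_native_grid_is_identity(self):
        t = np.arange(0, 5.0, 0.5)
        x = np.sin(t) * 50 + 60
        tr = self._tracks(t, x)
        out = resample(tr, 0.5)
        np.testing.assert_allclose(out.subject("r1")["x_cm"].to_numpy(), x, atol=1e-12)

    def test_shared_grid_ends_at_earliest_subject_end(self):
        df = pd.concat(
            [
                pd.DataFrame({"time_s": [0.0, 900.0], "subject_id": "r1", "x_cm": [0, 100], "y_cm": 10.0}),
                pd.DataFrame({"time_s": [0.0, 905.0], "subject_id": "r2", "x_cm": [0, 100], "y_cm": 30.0}),
            ],
            ignore_index=True,
        )
        from coopmaze.track_io import SessionTracks
        tr = SessionTracks(data=df, condition=ConditionSpec())
        out = resample(tr, 0.1)
        assert out.on_common_grid()
        assert out.subject("r2")["time_s"].iloc[-1] == pytest.approx(900.0)

    def test_interpolation_stays_in_neighbor_hull(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 30, 40))
        t[0] = 0.0
        x = rng.uniform(0, 120, 40)
        tr = self._tracks(t, x)
        out = resample(tr, 0.25)
        xo = out.subject("r1")["x_cm"].to_numpy()
        assert xo.min() >= x.min() - 1e-9 and xo.max() <= x.max() + 1e-9

    def test_long_gap_warns(self):
        tr = self._tracks([0.0, 5.0], [0.0, 50.0])
        with pytest.warns(UserWarning, match="gap"):
            resample(tr, 1.0)

    def test_bad_dt(self):
        tr = self._tracks([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            resample(tr, -0.1)


class TestEventLog:
    def _log(self):
        log = EventLog()
        log.append(Event(t_s=0.0, kind="trial_armed", zones=("A", "A")))
        log.append(Event(t_s=12.5, kind="reward", zones=("C", "C"),
                         reward_volume_ul=70.0, pump_duration_s=1.5))
        log.append(Event(t_s=40.0, kind="break", zones=("A", "C"), cause="two_zones_apart"))
        log.append(Event(t_s=900.0, kind="session_end", zones=("A", "B")))
        return log

    def test_empty_log_writes_header_only(self, tmp_path):
        f = tmp_path / "e.csv"
        write_events(EventLog(), f)
        assert f.read_text().count("\n") == 1
        assert len(read_events(f)) == 0

    @pytest.mark.parametrize("writer,reader", [
        (write_events, read_events),
        (write_events_jsonl, read_events_jsonl),
    ])
    def test_round_trip(self, tmp_path, writer, reader):
        log = self._log()
        f = tmp_path / "e.out"
        writer(log, f)
        back = reader(f)
        assert len(back) == len(log)
        for a, b in zip(back, log):
            assert (a.t_s, a.kind, a.zones, a.cause) == (b.t_s, b.kind, b.zones, b.cause)
        rw = back.of_kind("reward")[0]
        assert (rw.reward_volume_ul, rw.pump_duration_s) == (70.0, 1.5)

    def test_append_after_session_end_rejected(self):
        log = self._log()
        with pytest.raises(ValueError, match="session_end"):
            log.append(Event(t_s=901.0, kind="reward", zones=("C", "C")))

    def test_out_of_order_append_rejected(self):
        log = EventLog()
        log.append(Event(t_s=5.0, kind="trial_armed", zones=("A", "A")))
        with pytest.raises(ValueError, match="time order"):
            log.append(Event(t_s=4.0, kind="reward", zones=("C", "C")))


class TestFixtureFromZoneTimeline:
    def test_single_zone(self):
        tr = fixture_from_zone_timeline([[("A", 5.0)]], dt_s=0.1)
        z = zones_of(tr.subject("rat1")["x_cm"].to_numpy())
        assert set(z) == {"A"}
        assert len(z) == 50

    def test_transitions_at_requested_times(self):
        tr = fixture_from_zone_timeline([[("A", 5.0), ("B", 5.0), ("C", 5.0)]], dt_s=1.0)
        sub = tr.subject("rat1")
        z = zones_of(sub["x_cm"].to_numpy())
        assert list(z) == ["A"] * 5 + ["B"] * 5 + ["C"] * 5

    def test_round_trip_through_zone_of(self):
        rng = np.random.default_rng(11)
        tl = [("ABC"[int(rng.integers(3))], float(int(rng.integers(1, 40))) * 0.5)
              for _ in range(12)]
        tr = fixture_from_zone_timeline([tl], dt_s=0.5)
        z = zones_of(tr.subject("rat1")["x_cm"].to_numpy())
        # reconstruct the run-length encoding and compare
        recon, i = [], 0
        for j in range(1, len(z) + 1):
            if j == len(z) or z[j] != z[i]:
                recon.append((z[i], (j - i) * 0.5))
                i = j
        merged = []
        for zone, d in tl:  # merge adjacent equal zones as the fixture does
            if merged and merged[-1][0] == zone:
                merged[-1] = (zone, merged[-1][1] + d)
            else:
                merged.append((zone, d))
        assert recon == [(z, pytest.approx(d)) for z, d in merged]

    def test_dwell_not_multiple_of_dt_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            fixture_from_zone_timeline([[("A", 0.25)]], dt_s=0.1)

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError, match="zone"):
            fixture_from_zone_timeline([[("D", 1.0)]], dt_s=0.1)

    def test_unequal_durations_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            fixture_from_zone_timeline([[("A", 1.0)], [("A", 2.0)]], dt_s=0.1)
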
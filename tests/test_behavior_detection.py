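import numpy as np
import pandas as pd
import pytest

from hiveburst import behavior_detection as bh
from hiveburst.burst_detection import Burst
from conftest import make_meta, make_table, walk_rows


def heading_rows(bee, angles_deg, x=500.0, y=500.0, t0=0):
    rows = []
    for i, a in enumerate(angles_deg):
        rad = np.deg2rad(a)
        rows.append((bee, t0 + i, x, y, float(np.cos(rad)), float(np.sin(rad))))
    return rows


class TestDetectDances:
    def test_alternating_reversals_detected(self):
        angles = [0, 170, -20, 150, -40, 130]  # turns +170,-190->(+170),...
        angles = [0]
        for i in range(6):
            angles.append(angles[-1] + (170 if i % 2 == 0 else -170))
        table = make_table(heading_rows("D", angles))
        out = bh.detect_dances(table)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == len(angles) - 1

    def test_smooth_rotation_not_a_dance(self):
        angles = np.arange(0, 300, 30)  # 30 deg/s spin
        table = make_table(heading_rows("S", angles))
        assert len(bh.detect_dances(table)) == 0

    def test_same_direction_spin_fails_alternation(self):
        angles = np.arange(0, 8 * 170, 170)  # +170 deg every second
        table = make_table(heading_rows("P", angles))
        assert len(bh.detect_dances(table)) == 0

    def test_gap_in_tracking_breaks_window(self):
        angles = [0]
        for i in range(8):
            angles.append(angles[-1] + (170 if i % 2 == 0 else -170))
        rows = heading_rows("G", angles)
        del rows[4]  # missing second inside every candidate window
        rows = [(b, t, x, y, nx, ny) for (b, t, x, y, nx, ny) in rows]
        table = make_table(rows)
        out = bh.detect_dances(table)
        # windows containing the missing second are rejected; the tail
        # [5..9] still yields one window
        assert all(e - s + 1 >= 5 for _, s, e in
                   out[["bee_id", "start", "end"]].itertuples(index=False))

    def test_quiet_walkers_produce_no_dances(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            rows += walk_rows(f"W{i}", range(600), rng)
        table = make_table(rows)
        assert len(bh.detect_dances(table)) == 0


class TestDetectFollowers:
    def _dance_table_with(self, follower_rows):
        angles = [0]
        for i in range(10):
            angles.append(angles[-1] + (170 if i % 2 == 0 else -170))
        rows = heading_rows("DANCER", angles, x=1000.0, y=1000.0)
        rows += follower_rows
        return make_table(rows), bh.detect_dances(make_table(rows))

    def test_nearby_facing_bee_is_follower(self):
        fr = [("F", t, 1300.0, 1000.0, -1.0, 0.0) for t in range(11)]
        table, dances = self._dance_table_with(fr)
        out = bh.detect_followers(table, dances)
        assert len(out) == 1
        ev = out.iloc[0]
        assert ev["follower_id"] == "F" and ev["dancer_id"] == "DANCER"

    def test_facing_away_not_follower(self):
        fr = [("F", t, 1300.0, 1000.0, 1.0, 0.0) for t in range(11)]
        table, dances = self._dance_table_with(fr)
        assert len(bh.detect_followers(table, dances)) == 0

    def test_beyond_radius_not_follower(self):
        fr = [("F", t, 1700.0, 1000.0, -1.0, 0.0) for t in range(11)]
        table, dances = self._dance_table_with(fr)
        assert len(bh.detect_followers(table, dances)) == 0

    def test_follow_interval_inside_dance(self, dance_demo):
        _, table, _ = dance_demo
        dances = bh.detect_dances(table)
        follows = bh.detect_followers(table, dances)
        assert len(follows) > 0
        for ev in follows.itertuples(index=False):
            sub = dances[
                (dances["bee_id"] == ev.dancer_id)
                & (dances["start"] <= ev.start)
                & (dances["end"] >= ev.end)
            ]
            assert len(sub) == 1

    def test_rigid_motion_invariance(self):
        """Translating and rotating all coordinates and headings together
        leaves follow events unchanged."""
        angles = [0]
        for i in range(10):
            angles.append(angles[-1] + (170 if i % 2 == 0 else -170))
        rows = heading_rows("DANCER", angles, x=1000.0, y=1000.0)
        rows += [("F", t, 1300.0, 1000.0, -1.0, 0.0) for t in range(11)]
        phi = 0.7
        c, s = np.cos(phi), np.sin(phi)
        moved = []
        for bee, t, x, y, nx, ny in rows:
            xr = c * x - s * y + 800
            yr = s * x + c * y + 300
            moved.append((bee, t, xr, yr, c * nx - s * ny, s * nx + c * ny))
        t1 = make_table(rows)
        t2 = make_table(moved)
        out1 = bh.detect_followers(t1, bh.detect_dances(t1))
        out2 = bh.detect_followers(t2, bh.detect_dances(t2))
        pd.testing.assert_frame_equal(out1, out2)


class TestDetectTrips:
    def _table(self, present_times, T=3600, open_t=600):
        rows = [("B", t, 100.0, 100.0, 1.0, 0.0) for t in present_times]
        return make_table(rows, make_meta(T_total=T, entrance_open_t=open_t))

    def test_absence_before_entrance_is_not_trip(self):
        times = list(range(0, 100)) + list(range(500, 700))
        table = self._table(times)
        assert len(bh.detect_trips(table, table.meta)) == 0

    def test_absence_after_opening_is_trip(self):
        times = list(range(0, 700)) + list(range(820, 900))
        table = self._table(times)
        trips = bh.detect_trips(table, table.meta)
        assert len(trips) == 1
        assert trips.iloc[0]["exit_t"] == 699 and trips.iloc[0]["entry_t"] == 820

    def test_short_absence_below_min_gap_ignored(self):
        times = list(range(0, 700)) + list(range(730, 900))
        table = self._table(times)
        assert len(bh.detect_trips(table, table.meta, min_gap=60)) == 0


class TestFirstForagingDay:
    def _trips(self, exits):
        return pd.DataFrame(
            {"bee_id": "B", "exit_t": exits, "entry_t": [e + 120 for e in exits],
             "is_orientation": False}
        )

    def test_six_trips_third_before_noon_qualifies(self):
        # start 06:00 -> noon is t=21600; 2 of 6 before noon (33%)
        meta = make_meta(T_total=86400 * 2, entrance_open_t=600)
        exits = [7000, 9000, 30000, 35000, 40000, 45000]
        day = bh.first_foraging_day(self._trips(exits), meta)
        assert day == pd.Timestamp("2012-07-04")

    def test_one_sixth_before_noon_fails(self):
        meta = make_meta(T_total=86400 * 2, entrance_open_t=600)
        exits = [7000, 30000, 35000, 40000, 45000, 50000]
        assert bh.first_foraging_day(self._trips(exits), meta) is None

    def test_never_six_trips_returns_none(self):
        meta = make_meta(T_total=86400 * 2, entrance_open_t=600)
        assert bh.first_foraging_day(self._trips([7000, 9000]), meta) is None

    def test_monotone_adding_trips_never_delays(self):
        meta = make_meta(T_total=86400 * 3, entrance_open_t=600)
        rng = np.random.default_rng(0)
        exits = sorted(rng.integers(1000, 86400 * 3 - 1000, size=8).tolist())
        day0 = bh.first_foraging_day(self._trips(exits), meta)
        more = sorted(exits + [8000, 8100, 8200, 8300, 8400, 8500])
        day1 = bh.first_foraging_day(self._trips(more), meta)
        if day0 is not None:
            assert day1 is not None and day1 <= day0


class TestOrientationFlags:
    def test_skip_n_rule(self):
        meta = make_meta(T_total=86400, entrance_open_t=600)
        trips = pd.DataFrame(
            {"bee_id": "B", "exit_t": np.arange(1000, 1800, 100),
             "entry_t": np.arange(1080, 1880, 100), "is_orientation": False}
        )
        out = bh.flag_orientation_trips(trips, meta, rule="skip-n", skip_first_n=6)
        assert out["is_orientation"].tolist() == [True] * 6 + [False] * 2

    def test_first_day_rule_flags_pre_qualifying_days(self):
        meta = make_meta(T_total=86400 * 2, entrance_open_t=600)
        # day 1: 3 trips (no quorum) -> orientation; day 2: 6 trips, 3 am
        exits = [20000, 30000, 40000] + [86400 + e for e in
                                         (7000, 9000, 11000, 30000, 35000, 40000)]
        trips = pd.DataFrame(
            {"bee_id": "B", "exit_t": exits,
             "entry_t": [e + 60 for e in exits], "is_orientation": False}
        )
        out = bh.flag_orientation_trips(trips, meta)
        assert out["is_orientation"].tolist() == [True] * 3 + [False] * 6


class TestLabelBurstRoles:
    def _roles(self, trips=None, dances=None, follows=None):
        empty_t = pd.DataFrame(
            columns=["bee_id", "exit_t", "entry_t", "is_orientation"]
        )
        empty_d = pd.DataFrame(columns=["bee_id", "start", "end"])
        empty_f = pd.DataFrame(columns=["follower_id", "dancer_id", "start", "end"])
        burst = Burst(0, 4900, 5100, 5000, 9.0)
        return bh.label_burst_roles(
            [burst],
            trips if trips is not None else empty_t,
            dances if dances is not None else empty_d,
            follows if follows is not None else empty_f,
        )

    def test_trip_entry_in_window_is_forager(self):
        trips = pd.DataFrame(
            [("B1", 4000, 4300, False)],
            columns=["bee_id", "exit_t", "entry_t", "is_orientation"],
        )
        out = self._roles(trips=trips)
        assert out.iloc[0].tolist() == [0, "F", "B1"]

    def test_trip_entry_outside_window_excluded(self):
        trips = pd.DataFrame(
            [("B1", 4000, 4700, False)],  # entry 300 s before peak
            columns=["bee_id", "exit_t", "entry_t", "is_orientation"],
        )
        assert len(self._roles(trips=trips)) == 0

    def test_orientation_trip_excluded(self):
        trips = pd.DataFrame(
            [("B1", 4000, 4300, True)],
            columns=["bee_id", "exit_t", "entry_t", "is_orientation"],
        )
        assert len(self._roles(trips=trips)) == 0

    def test_dancer_and_follower_windows(self):
        dances = pd.DataFrame(
            [("W1", 4500, 4600), ("W2", 5200, 5300)],
            columns=["bee_id", "start", "end"],
        )
        follows = pd.DataFrame(
            [("DF1", "W1", 4550, 4590)],
            columns=["follower_id", "dancer_id", "start", "end"],
        )
        out = self._roles(dances=dances, follows=follows)
        got = set(map(tuple, out[["role", "bee_id"]].to_numpy()))
        assert got == {("W", "W1"), ("DF", "DF1")}
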
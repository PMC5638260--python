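import io
import math

import numpy as np
import pandas as pd
import pytest

import encounternet as en
from encounternet.checkins import _TIME_FORMAT


def make_table(rows):
    """rows: (user, iso_utc_time, lat, lon) tuples -> CheckinTable."""
    df = pd.DataFrame(rows, columns=["user_id", "utc_time", "lat", "lon"])
    df["utc_time"] = pd.to_datetime(df["utc_time"], utc=True)
    df["tz_offset"] = 0
    df["venue_id"] = "v"
    df["venue_category"] = "c"
    return en.CheckinTable(df)


class TestReadCheckins:
    def test_round_trip_via_tsv(self, tmp_path, small_synthetic_table):
        p = tmp_path / "checkins.tsv"
        en.write_tsv(small_synthetic_table, p)
        back = en.read_checkins(p)
        assert len(back) == len(small_synthetic_table)
        assert back.n_malformed == 0
        assert back.n_users == small_synthetic_table.n_users

    def test_malformed_rows_counted_not_silently_dropped(self, tmp_path):
        p = tmp_path / "bad.tsv"
        good = "u1\tv1\tc\tCafe\t40.7\t-74.0\t-240\tTue Apr 03 18:00:09 +0000 2012"
        bad = "u2\tv2\tc\tCafe\t999.0\t-74.0\t-240\tTue Apr 03 18:00:09 +0000 2012"
        ugly = "u3\tv3\tc\tCafe\t40.7\t-74.0\t-240\tnot a time"
        p.write_text("\n".join([good, bad, ugly]) + "\n")
        with pytest.warns(UserWarning, match="malformed"):
            table = en.read_checkins(p)
        assert len(table) == 1
        assert table.n_malformed == 2

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.warns(UserWarning):
            table = en.read_checkins(p)
        assert len(table) == 0


class TestIntereventAndDisplacement:
    def test_simple_gap(self):
        t = make_table([("u", "2012-05-01 10:00", 40.7, -74.0),
                        ("u", "2012-05-01 13:30", 40.7, -74.0)])
        assert en.interevent_times(t).tolist() == [3.5]
        assert en.displacements(t).tolist() == [0.0]

    def test_single_checkin_users_contribute_nothing(self):
        t = make_table([("a", "2012-05-01 10:00", 40.7, -74.0),
                        ("b", "2012-05-01 11:00", 40.8, -74.0)])
        assert en.interevent_times(t).size == 0
        assert en.displacements(t).size == 0

    def test_one_degree_latitude_displacement(self):
        t = make_table([("u", "2012-05-01 10:00", 0.0, 0.0),
                        ("u", "2012-05-01 11:00", 1.0, 0.0)])
        r = en.displacements(t)
        assert r[0] == pytest.approx(6371.0 * math.pi / 180.0, rel=1e-9)

    def test_gaps_never_cross_users(self):
        t = make_table([("a", "2012-05-01 00:00", 0.0, 0.0),
                        ("a", "2012-05-01 01:00", 0.0, 0.0),
                        ("b", "2012-05-01 00:30", 0.0, 0.0),
                        ("b", "2012-05-01 02:30", 0.0, 0.0)])
        assert sorted(en.interevent_times(t).tolist()) == [1.0, 2.0]


class TestPowerLawFits:
    def test_closed_form_exponent_two(self):
        # fixed x_min = 1, all samples at e: alpha = 1 + n / sum ln x = 2
        from encounternet.checkins import _mle_exponent
        x = np.full(3, math.e)
        assert _mle_exponent(x, 1.0) == pytest.approx(2.0)

    def test_recovers_planted_pareto_exponents(self):
        rng = np.random.default_rng(10)
        for gamma in (1.5, 2.5, 3.5):
            x = 1.0 * rng.random(30_000) ** (-1.0 / (gamma - 1.0))
            fit = en.fit_power_law_xmin(x)
            assert fit.exponent == pytest.approx(gamma, abs=0.06)
            assert fit.n_tail >= 1000

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            en.fit_power_law_xmin(np.ones(10))

    def test_range_fit_recovers_truncated_exponent(self):
        rng = np.random.default_rng(11)
        lo, hi, delta = 0.001, 10.0, 1.15
        a = 1 - delta
        u = rng.random(50_000)
        x = (lo ** a + u * (hi ** a - lo ** a)) ** (1 / a)
        fit = en.fit_power_law_range(x, lo, hi)
        assert fit.exponent == pytest.approx(delta, abs=0.05)

    def test_range_fit_degenerate_sample(self):
        with pytest.raises(ValueError):
            en.fit_power_law_range(np.full(100, 2.0), 1.0, 10.0)
        with pytest.raises(ValueError):
            en.fit_power_law_range(np.ones(100), 5.0, 1.0)


class TestHourlyCocoincidences:
    def test_single_user_empty(self):
        t = make_table([("u", "2012-05-01 10:00", 40.7, -74.0)])
        co = en.hourly_cocoincidences(t, 100.0)
        assert co.events == {}

    def test_same_venue_same_hour_counts_once(self):
        t = make_table([("a", "2012-05-01 14:10", 40.7, -74.0),
                        ("b", "2012-05-01 14:50", 40.7, -74.0)])
        co = en.hourly_cocoincidences(t, 100.0)
        assert co.counts() == {(0, 1): 1}

    def test_burst_in_one_hour_still_counts_once(self):
        rows = [("a", f"2012-05-01 14:{m:02d}", 40.7, -74.0) for m in (1, 2, 3)]
        rows += [("b", f"2012-05-01 14:{m:02d}", 40.7, -74.0) for m in (4, 5)]
        co = en.hourly_cocoincidences(make_table(rows), 50.0)
        assert co.counts() == {(0, 1): 1}

    def test_hour_boundary_separates_bins(self):
        t = make_table([("a", "2012-05-01 14:59", 40.7, -74.0),
                        ("b", "2012-05-01 15:01", 40.7, -74.0)])
        assert en.hourly_cocoincidences(t, 100.0).events == {}

    def test_local_hour_binning_uses_tz_offset(self):
        # 18:30 and 19:10 UTC fall in different UTC hours, but with a
        # +30 min offset both land in the same local hour (19:00-20:00)
        df = make_table([("a", "2012-05-01 18:40", 40.7, -74.0),
                         ("b", "2012-05-01 19:10", 40.7, -74.0)]).records
        df["tz_offset"] = 30
        t = en.CheckinTable(df)
        assert en.hourly_cocoincidences(t, 100.0, local_hours=True).counts() == {(0, 1): 1}
        assert en.hourly_cocoincidences(t, 100.0, local_hours=False).events == {}

    def test_distance_threshold_applies(self):
        # ~157 m apart at the equator (0.001 deg lat ~ 111 m)
        t = make_table([("a", "2012-05-01 14:00", 0.0, 0.0),
                        ("b", "2012-05-01 14:30", 0.0011, 0.0)])
        assert en.hourly_cocoincidences(t, 100.0).events == {}
        assert en.hourly_cocoincidences(t, 200.0).counts() == {(0, 1): 1}

    def test_five_user_schedule_matches_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        for u in range(5):
            for _ in range(30):
                h = int(rng.integers(0, 72))
                m = int(rng.integers(0, 60))
                lat = 40.7 + float(rng.integers(0, 4)) * 0.0005
                rows.append((f"u{u}", pd.Timestamp("2012-05-01") +
                             pd.Timedelta(hours=h, minutes=m), lat, -74.0))
        t = make_table(rows)
        co = en.hourly_cocoincidences(t, 100.0)
        orc = en.brute_force_cocoincidence_oracle(t, 100.0)
        assert {p: list(v) for p, v in co.events.items()} == \
               {p: list(v) for p, v in orc.events.items()}

    def test_delta_r_monotonicity(self, small_synthetic_table):
        c1 = en.hourly_cocoincidences(small_synthetic_table, 50.0).counts()
        c2 = en.hourly_cocoincidences(small_synthetic_table, 200.0).counts()
        for pair, n in c1.items():
            assert c2.get(pair, 0) >= n


class TestCoincidenceFrequency:
    def test_hand_counts(self):
        co = en.CoincidenceTable(["a", "b", "c"], {
            (0, 1): np.array([1]), (0, 2): np.array([4]),
            (1, 2): np.array([2, 7])}, 100.0)
        assert en.coincidence_frequency(co) == {1: 2, 2: 1}

    def test_conservation(self, small_synthetic_table):
        co = en.hourly_cocoincidences(small_synthetic_table, 100.0)
        f = en.coincidence_frequency(co)
        assert sum(f.values()) == len(co.events)


class TestCumulativeNetwork:
    def test_link_appears_and_never_vanishes(self):
        co = en.CoincidenceTable(["a", "b"], {(0, 1): np.array([5, 9])}, 100.0)
        assert en.cumulative_network(co, 2, 4)[0, 1] == 0
        assert en.cumulative_network(co, 2, 8)[0, 1] == 0
        assert en.cumulative_network(co, 2, 9)[0, 1] == 1
        assert en.cumulative_network(co, 2, 10 ** 9)[0, 1] == 1

    def test_threshold_nesting(self, small_synthetic_table):
        co = en.hourly_cocoincidences(small_synthetic_table, 100.0)
        t = 10 ** 9
        A1 = en.cumulative_network(co, 1, t)
        A3 = en.cumulative_network(co, 3, t)
        assert ((A3 == 1) <= (A1 == 1)).all()

    def test_mean_degree_monotone_on_grid(self, small_synthetic_table):
        co = en.hourly_cocoincidences(small_synthetic_table, 100.0)
        bins = sorted({b for v in co.events.values() for b in v})
        if len(bins) < 2:
            pytest.skip("too few distinct co-coincidence hours")
        grid = np.asarray(bins)
        mk, _ = en.temporal_curves(co, 1, grid)
        assert (np.diff(mk) >= -1e-12).all()

    def test_empty_events_flat_zero(self):
        co = en.CoincidenceTable(["a", "b"], {}, 100.0)
        mk, mC = en.temporal_curves(co, 1, np.arange(5))
        assert (mk == 0).all() and (mC == 0).all()


class TestLargestComponentSummary:
    def test_triangle(self):
        K3 = np.ones((3, 3)) - np.eye(3)
        s = en.largest_component_summary(K3)
        assert (s.size, s.edges, s.diameter) == (3, 3, 1)
        assert s.mean_degree == pytest.approx(2.0)
        assert s.mean_clustering == pytest.approx(1.0)
        assert s.mean_distance == pytest.approx(1.0)

    def test_path_of_four(self):
        A = np.zeros((4, 4), dtype=int)
        for i in range(3):
            A[i, i + 1] = A[i + 1, i] = 1
        s = en.largest_component_summary(A)
        assert s.diameter == 3
        assert s.mean_distance == pytest.approx(10 / 6)

    def test_empty_graph_returns_none(self):
        assert en.largest_component_summary(np.zeros((5, 5))) is None

    def test_picks_largest_component(self):
        A = np.zeros((6, 6), dtype=int)
        A[0, 1] = A[1, 0] = 1                     # dyad
        for i, j in [(2, 3), (3, 4), (4, 5), (5, 2)]:  # 4-cycle
            A[i, j] = A[j, i] = 1
        s = en.largest_component_summary(A)
        assert s.size == 4 and s.edges == 4
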
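import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liondens import trajectory as ldtraj
from liondens.trajectory import (
    Trajectory,
    daily_net_displacement,
    detect_clusters,
    duration_of_stay,
    haversine_km,
    step_lengths,
)

from _oracles import clusters_oracle
from conftest import make_traj

DEG_TO_M = 111_194.9  # metres per degree of latitude at R = 6371.0088 km


class TestStepLengths:
    def test_identical_coordinates_give_zero(self):
        traj = make_traj([31.5, 31.5], [-24.9, -24.9])
        assert step_lengths(traj)["distance_km"].iloc[0] == 0.0

    def test_one_hundredth_degree_of_latitude(self):
        traj = make_traj([0.0, 0.0], [0.0, 0.01])
        d = step_lengths(traj)["distance_km"].iloc[0]
        assert d == pytest.approx(1.1119, abs=1e-4)

    def test_three_fixes_give_two_steps(self):
        traj = make_traj([31.0, 31.1, 31.2], [-24.0, -24.0, -24.0])
        assert len(step_lengths(traj)) == 2

    def test_single_fix_gives_empty_frame(self):
        traj = make_traj([31.0], [-24.0])
        out = step_lengths(traj)
        assert out.empty and "distance_km" in out.columns


class TestHaversine:
    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(*[st.floats(-179, 179) for _ in range(3)]),
           st.tuples(*[st.floats(-80, 80) for _ in range(3)]))
    def test_symmetry_and_triangle_inequality(self, lons, lats):
        a, b, c = zip(lons, lats)
        dab = haversine_km(a[0], a[1], b[0], b[1])
        dba = haversine_km(b[0], b[1], a[0], a[1])
        dac = haversine_km(a[0], a[1], c[0], c[1])
        dcb = haversine_km(c[0], c[1], b[0], b[1])
        assert dab == pytest.approx(dba, rel=1e-12)
        assert dab <= dac + dcb + 1e-9


class TestTrajectoryValidation:
    def test_rejects_nonincreasing_timestamps(self):
        t = pd.to_datetime(["2011-01-01", "2011-01-01"], utc=True)
        with pytest.raises(ValueError):
            Trajectory("F1", pd.DataFrame({"t": t, "lon": [0, 0], "lat": [0, 0]}))

    def test_rejects_out_of_bounds_latitude(self):
        t = pd.date_range("2011-01-01", periods=2, freq="4h", tz="UTC")
        with pytest.raises(ValueError):
            Trajectory("F1", pd.DataFrame({"t": t, "lon": [0, 0], "lat": [0, 95]}))


class TestDailyNetDisplacement:
    def test_stationary_female_moves_zero(self):
        traj = make_traj([31.5] * 12, [-24.9] * 12)
        assert (daily_net_displacement(traj) == 0).all()

    def test_mean_and_sum_of_known_steps(self):
        # steps of 1, 2 and 3 km northward within one civil day
        km = 1.0 / 111.1949
        lats = np.cumsum([0.0, 1 * km, 2 * km, 3 * km]) - 25.0
        traj = make_traj([31.0] * 4, lats, start="2011-01-01 00:00")
        mean = daily_net_displacement(traj, how="mean")
        total = daily_net_displacement(traj, how="sum")
        assert mean.iloc[0] == pytest.approx(2.0, rel=1e-4)
        assert total.iloc[0] == pytest.approx(6.0, rel=1e-4)

    def test_steps_assigned_to_day_of_later_fix_at_local_boundary(self):
        # civil day boundary at UTC+2 = 22:00 UTC; a step ending 21:00
        # belongs to Jan 1 (local), a step ending 01:00 to Jan 2
        t = pd.to_datetime(["2011-01-01 17:00", "2011-01-01 21:00",
                            "2011-01-02 01:00"], utc=True)
        km = 1.0 / 111.1949
        df = pd.DataFrame({"t": t, "lon": [31.0, 31.0, 31.0],
                           "lat": [-25.0, -25.0 + km, -25.0 + 3 * km]})
        out = daily_net_displacement(Trajectory("F1", df), how="sum")
        assert list(out.index.astype(str)) == ["2011-01-01", "2011-01-02"]
        assert out.iloc[0] == pytest.approx(1.0, rel=1e-4)
        assert out.iloc[1] == pytest.approx(2.0, rel=1e-4)


class TestDetectClusters:
    def test_tight_fixes_form_single_cluster(self):
        rng = np.random.default_rng(0)
        n = 30
        lon = 31.5 + rng.normal(0, 30 / DEG_TO_M, n)  # ~30 m scatter
        lat = -24.9 + rng.normal(0, 30 / DEG_TO_M, n)
        clusters = detect_clusters(make_traj(lon, lat))
        assert len(clusters) == 1
        assert clusters[0].n_fixes == n
        assert clusters[0].max_radius_m <= 200

    def test_alternating_km_jumps_give_no_clusters(self):
        lat = [-24.9, -24.9 + 1000 / DEG_TO_M] * 5
        assert detect_clusters(make_traj([31.5] * 10, lat)) == []

    def test_min_fixes_threshold(self):
        # two tight fixes then a jump: kept only at min_fixes <= 2
        lat = [-24.9, -24.9, -24.0, -24.0]
        clusters3 = detect_clusters(make_traj([31.5] * 4, lat), min_fixes=3)
        clusters2 = detect_clusters(make_traj([31.5] * 4, lat), min_fixes=2)
        assert len(clusters3) == 0 and len(clusters2) == 2

    def test_first_fix_anchor_option(self):
        # drifting fixes 150 m apart: each stays within 200 m of its
        # predecessor's centroid but drifts >200 m from the first fix
        lat = -24.9 + np.arange(6) * 120 / DEG_TO_M
        traj = make_traj([31.5] * 6, lat)
        by_centroid = detect_clusters(traj, anchor="centroid", min_fixes=2)
        by_first = detect_clusters(traj, anchor="first", min_fixes=2)
        assert max(c.n_fixes for c in by_first) < max(
            c.n_fixes for c in by_centroid)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters(make_traj([31.5, 31.5], [-24.9, -24.9]), radius_m=0)

    def test_gap_does_not_break_cluster(self):
        rng = np.random.default_rng(1)
        n = 24
        lon = 31.5 + rng.normal(0, 20 / DEG_TO_M, n)
        lat = -24.9 + rng.normal(0, 20 / DEG_TO_M, n)
        t = pd.date_range("2011-01-01", periods=n, freq="4h", tz="UTC")
        full = pd.DataFrame({"t": t, "lon": lon, "lat": lat})
        gappy = full.drop(index=[5, 6, 7, 12]).reset_index(drop=True)
        clusters = detect_clusters(Trajectory("F1", gappy))
        assert len(clusters) == 1
        assert clusters[0].n_fixes == n - 4

    def test_shrinking_radius_never_grows_largest_cluster(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            step = rng.uniform(50, 400, 40) / DEG_TO_M
            lat = -24.9 + np.cumsum(step * rng.choice([-1, 1], 40))
            traj = make_traj([31.5] * 40, lat)
            sizes = []
            for r in (400.0, 200.0, 100.0):
                cl = detect_clusters(traj, radius_m=r, min_fixes=1)
                sizes.append(max((c.n_fixes for c in cl), default=0))
            assert sizes[0] >= sizes[1] >= sizes[2]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            # mixture of tight jitter and occasional jumps
            step_m = rng.choice([15.0, 600.0], n, p=[0.8, 0.2])
            ang = rng.uniform(0, 2 * np.pi, n)
            lon = 31.5 + np.cumsum(step_m * np.cos(ang)) / DEG_TO_M
            lat = -24.9 + np.cumsum(step_m * np.sin(ang)) / DEG_TO_M
            traj = make_traj(lon, lat)
            got = detect_clusters(traj)
            expected = clusters_oracle(list(lon), list(lat))
            assert len(got) == len(expected)
            t = traj.t
            for c, (i, j) in zip(got, expected):
                assert c.start_t == pd.Timestamp(t[i])
                assert c.end_t == pd.Timestamp(t[j])
                assert c.n_fixes == j - i + 1

    def test_clusters_are_disjoint_and_ordered(self, small_study):
        for traj in small_study.trajectories.values():
            clusters = detect_clusters(traj)
            for a, b in zip(clusters, clusters[1:]):
                assert a.end_t < b.start_t


class TestDurationOfStay:
    def _cluster(self, days, start="2011-02-01"):
        s = pd.Timestamp(start, tz="UTC")
        return ldtraj.ResidencyCluster("F1", s, s + pd.Timedelta(days=days),
                                       31.5, -24.9, 10, 50.0)

    def test_single_long_cluster(self):
        out = duration_of_stay([self._cluster(19.7)])
        assert out["mean_days"] == pytest.approx(19.7)
        assert out["max_days"] == pytest.approx(19.7)
        assert out["count"] == 1

    def test_no_clusters_flagged_by_zero_count(self):
        out = duration_of_stay([])
        assert out["count"] == 0 and np.isnan(out["mean_days"])

    def test_mean_of_two_clusters(self):
        out = duration_of_stay([self._cluster(4.0), self._cluster(6.0, "2011-04-01")])
        assert out["mean_days"] == pytest.approx(5.0)

    def test_window_restriction(self):
        clusters = [self._cluster(4.0, "2011-02-01"),
                    self._cluster(6.0, "2011-05-01")]
        out = duration_of_stay(
            clusters,
            pd.Timestamp("2011-05-01", tz="UTC"),
            pd.Timestamp("2011-05-31", tz="UTC"),
        )
        assert out["count"] == 1 and out["mean_days"] == pytest.approx(6.0)
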
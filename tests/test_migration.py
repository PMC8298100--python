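import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import curve_fit

from vesiquant.migration import (
    Track,
    average_speed,
    cumulative_distance,
    direction_autocorrelation,
    directionality_ratio,
    fastest_segment_time,
    instantaneous_speed,
    msd,
    read_tracks,
    superplot_summary,
    turning_angles,
    write_tracks,
)
from vesiquant.synth import TrackSimParams, simulate_tracks

from conftest import straight_track


def track_from_points(points, dt=1.0):
    pts = np.asarray(points, float)
    return Track(cell_id="c", t=np.arange(len(pts)) * dt, xy=pts)


@pytest.fixture
def l_track():
    # 3 um east then 4 um north, 1 um per minute
    pts = [(x, 0.0) for x in range(4)] + [(3.0, y) for y in range(1, 5)]
    return track_from_points(pts)


class TestBasicStats:
    def test_straight_track_constant_speed(self):
        tr = straight_track(v=0.4)
        assert np.allclose(instantaneous_speed(tr), 0.4)
        assert average_speed(tr) == pytest.approx(0.4)

    def test_3_4_5_triangle_speed(self):
        tr = track_from_points([(0, 0), (3, 4)])
        assert instantaneous_speed(tr)[0] == pytest.approx(5.0)

    def test_stationary_cell_zero(self):
        tr = track_from_points([(1, 1)] * 5)
        assert np.allclose(instantaneous_speed(tr), 0.0)

    def test_cumulative_distance_hand_case(self):
        tr = track_from_points([(0, 0), (3, 4), (6, 8)])
        assert cumulative_distance(tr).tolist() == [0.0, 5.0, 10.0]
        assert average_speed(tr) == pytest.approx(5.0)

    def test_back_and_forth_counts_path(self):
        tr = track_from_points([(0, 0), (1, 0), (0, 0), (1, 0), (0, 0)])
        assert cumulative_distance(tr)[-1] == pytest.approx(4.0)

    def test_cohort_speed_recovery(self):
        tracks = simulate_tracks(
            TrackSimParams(n_cells=200, mean_speed=0.5, seed=10)
        )
        mean = np.mean([average_speed(t) for t in tracks])
        assert mean == pytest.approx(0.5, rel=0.05)


class TestDirectionalityRatio:
    def test_straight_track_always_one(self):
        dr = directionality_ratio(straight_track())
        assert np.allclose(dr[1:], 1.0)
        assert np.isnan(dr[0])

    def test_out_and_back_ends_at_zero(self):
        tr = track_from_points([(0, 0), (2, 0), (0, 0)])
        assert directionality_ratio(tr)[-1] == pytest.approx(0.0)

    def test_l_shape_final_value(self, l_track):
        assert directionality_ratio(l_track)[-1] == pytest.approx(5.0 / 7.0)

    def test_never_exceeds_one(self, rng):
        for _ in range(10):
            tr = track_from_points(np.cumsum(rng.normal(0, 1, (20, 2)), axis=0))
            dr = directionality_ratio(tr)
            assert np.nanmax(dr) <= 1.0 + 1e-12


class TestMsd:
    def test_ballistic_closed_form(self):
        v = 0.7
        tr = straight_track(v=v, n=21)
        table = msd([tr])
        assert np.allclose(table["mean"], (v * table["lag_time"]) ** 2)

    def test_lag_one_equals_mean_squared_step(self, rng):
        tr = track_from_points(np.cumsum(rng.normal(0, 1, (30, 2)), axis=0))
        table = msd([tr])
        expected = np.mean(tr.step_lengths() ** 2)
        assert table.loc[table["lag"] == 1, "mean"].iloc[0] == pytest.approx(expected)

    def test_brownian_slope_4d(self, rng):
        # 2D Brownian positions with per-axis step var 2*D*dt -> MSD = 4*D*t
        D, dt, n = 0.02, 1.0, 101
        tracks = []
        for i in range(200):
            steps = rng.normal(0, np.sqrt(2 * D * dt), (n - 1, 2))
            xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            tracks.append(Track(cell_id=str(i), t=np.arange(n) * dt, xy=xy))
        table = msd(tracks, max_lag_fraction=0.2)
        slope = np.polyfit(table["lag_time"], table["mean"], 1)[0]
        assert slope == pytest.approx(4 * D, rel=0.1)


class TestDirectionAutocorrelation:
    def test_straight_track_all_ones(self):
        table = direction_autocorrelation([straight_track(n=21)])
        assert np.allclose(table["mean"], 1.0)

    def test_zigzag_alternating_90deg(self):
        pts, pos = [(0.0, 0.0)], np.zeros(2)
        for i in range(12):
            pos = pos + ([1, 0] if i % 2 == 0 else [0, 1])
            pts.append(tuple(pos))
        table = direction_autocorrelation([track_from_points(pts)])
        by_lag = table.set_index("lag")["mean"]
        assert by_lag[0] == 1.0
        assert by_lag[1] == pytest.approx(0.0, abs=1e-12)
        assert by_lag[2] == pytest.approx(1.0)

    def test_prw_decay_rate_matches_persistence(self):
        P = 8.0
        tracks = simulate_tracks(
            TrackSimParams(
                n_cells=200, persistence_time=P, frame_interval=2.0,
                duration=200.0, seed=3,
            )
        )
        table = direction_autocorrelation(tracks, max_lag_fraction=0.3)
        sub = table[table["lag_time"] <= 3 * P]
        popt, _ = curve_fit(
            lambda t, tau: np.exp(-t / tau), sub["lag_time"], sub["mean"],
            p0=[P],
        )
        assert popt[0] == pytest.approx(P, rel=0.2)


class TestTurningAngles:
    def test_straight_track_zero(self):
        assert np.allclose(turning_angles([straight_track()]), 0.0)

    def test_ccw_square_path(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0), (1, 0)]
        angles = turning_angles([track_from_points(pts)])
        assert np.allclose(angles, np.pi / 2)

    def test_isotropic_walk_uniform_histogram(self, rng):
        headings = rng.uniform(0, 2 * np.pi, 10_001)
        steps = np.column_stack([np.cos(headings), np.sin(headings)])
        tr = track_from_points(np.vstack([[0, 0], np.cumsum(steps, axis=0)]))
        angles = turning_angles([tr])
        counts, _ = np.histogram(angles, bins=18, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_reflection_flips_sign(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (15, 2)), axis=0)
        a = turning_angles([track_from_points(xy)])
        mirrored = xy * np.array([1.0, -1.0])
        b = turning_angles([track_from_points(mirrored)])
        assert np.allclose(a, -b)


class TestFastestSegment:
    def test_straight_track_exact(self):
        tr = straight_track(v=1.0, n=31)
        assert fastest_segment_time(tr, 25.0) == pytest.approx(25.0)

    def test_discrete_window_rounding(self):
        tr = straight_track(v=2.0, n=31)
        # 13 steps x 2 um = 26 um is the first window reaching >= 25
        assert fastest_segment_time(tr, 25.0) == pytest.approx(13.0)

    def test_short_track_undefined(self):
        tr = straight_track(v=1.0, n=11)  # total path 10 um
        assert np.isnan(fastest_segment_time(tr, 25.0))


class TestRigidMotionInvariance:
    def test_statistics_invariant(self, rng):
        tracks = simulate_tracks(TrackSimParams(n_cells=10, seed=5))
        theta = 0.83
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([12.3, -4.5])
        moved = [
            Track(cell_id=t.cell_id, t=t.t, xy=t.xy @ R.T + shift,
                  experiment_id=t.experiment_id, condition=t.condition)
            for t in tracks
        ]
        for orig, mv in zip(tracks, moved):
            assert average_speed(orig) == pytest.approx(average_speed(mv))
            assert np.allclose(
                directionality_ratio(orig)[1:], directionality_ratio(mv)[1:]
            )
        assert np.allclose(msd(tracks)["mean"], msd(moved)["mean"])
        assert np.allclose(turning_angles(tracks), turning_angles(moved))

    def test_path_at_least_net_displacement(self, rng):
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 1, (15, 2)), axis=0)
            tr = track_from_points(xy)
            net = np.hypot(*(xy[-1] - xy[0]))
            assert cumulative_distance(tr)[-1] >= net - 1e-12


class TestSuperplot:
    @staticmethod
    def cohort(effects, n_exp=4, n_cells=30, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cond, mean in effects.items():
            for e in range(n_exp):
                shift = rng.normal(0, noise)
                for i in range(n_cells):
                    rows.append(
                        {
                            "condition": cond,
                            "experiment_id": f"e{e}",
                            "cell_id": f"{cond}{e}{i}",
                            "average_speed": rng.normal(mean + shift, 0.05),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_experiment_means_p_one(self):
        rows = []
        for cond in ("a", "b"):
            for e in range(3):
                rows.append(
                    {"condition": cond, "experiment_id": f"e{e}",
                     "average_speed": 0.4}
                )
        out = superplot_summary(pd.DataFrame(rows), "average_speed")
        assert out["test"]["p"] == pytest.approx(1.0)
        assert out["test"]["difference"] == pytest.approx(0.0)

    def test_planted_effect_direction(self):
        df = self.cohort({"ctrl": 0.40, "kd": 0.32}, seed=2)
        out = superplot_summary(df, "average_speed")
        # conditions sorted: ctrl - kd difference should be positive... but
        # sorted order is ['ctrl', 'kd'], difference = mean(ctrl) - mean(kd)
        assert out["test"]["difference"] > 0
        assert out["test"]["p"] < 0.05

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(40):
            df = self.cohort({"a": 0.4, "b": 0.4}, n_exp=4, seed=100 + rep)
            pvals.append(superplot_summary(df, "average_speed")["test"]["p"])
        # KS against uniform; generous threshold for 40 reps
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_three_conditions_delegate_to_dunnett(self):
        df = self.cohort({"ctrl": 0.4, "kd1": 0.3, "kd2": 0.4}, seed=4)
        out = superplot_summary(df, "average_speed", control="ctrl")
        assert out["test"]["method"] == "dunnett_experiment_means"
        assert set(out["test"]["p"]) == {"kd1", "kd2"}

    def test_single_experiment_t_rejected(self):
        rows = [
            {"condition": c, "experiment_id": "e0", "average_speed": v}
            for c, v in (("a", 0.4), ("b", 0.3))
        ]
        with pytest.raises(ValueError, match="experiment"):
            superplot_summary(pd.DataFrame(rows), "average_speed")


class TestReaders:
    def test_tidy_round_trip(self, tmp_path):
        tracks = simulate_tracks(TrackSimParams(n_cells=3, seed=1))
        path = tmp_path / "tracks.csv"
        write_tracks(tracks, path)
        back = read_tracks(path, frame_interval=tracks[0].frame_interval)
        assert len(back) == 3
        for a, b in zip(tracks, sorted(back, key=lambda t: t.cell_id)):
            assert np.allclose(a.xy, b.xy)
            assert np.allclose(a.t, b.t)

    def test_fiji_manual_tracking_dialect(self):
        text = (
            " ,Track n°,Slice n°,X,Y,Distance,Velocity,Pixel Value\n"
            "1,1,1,10,20,0,0,100\n"
            "2,1,2,13,24,5,5,101\n"
            "3,2,1,0,0,0,0,90\n"
            "4,2,2,8,6,10,10,91\n"
        )
        tracks = read_tracks(io.StringIO(text), frame_interval=10.0,
                             pixel_size=0.5)
        assert len(tracks) == 2
        assert np.allclose(tracks[0].xy, [[5.0, 10.0], [6.5, 12.0]])
        assert tracks[0].t.tolist() == [10.0, 20.0]

    def test_unrecognized_table_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            read_tracks(io.StringIO("a,b\n1,2\n"), frame_interval=1.0)


class TestParameterRecovery:
    def test_prw_grid_speed_and_persistence(self):
        # 3x3 grid scaled down to 2x2 corners + centre to stay in budget
        grid = [(0.3, 5.0), (0.3, 20.0), (0.6, 5.0), (0.6, 20.0), (0.45, 10.0)]
        for i, (speed, persistence) in enumerate(grid):
            tracks = simulate_tracks(
                TrackSimParams(
                    n_cells=200, mean_speed=speed, persistence_time=persistence,
                    frame_interval=2.0, duration=160.0,
                    speed_sd_between_cells=0.02, seed=50 + i,
                )
            )
            est_speed = np.mean([average_speed(t) for t in tracks])
            table = direction_autocorrelation(tracks, max_lag_fraction=0.4)
            sub = table[table["lag_time"] <= 3 * persistence]
            popt, _ = curve_fit(
                lambda t, tau: np.exp(-t / tau), sub["lag_time"], sub["mean"],
                p0=[persistence],
            )
            assert est_speed == pytest.approx(speed, rel=0.2)
            assert popt[0] == pytest.approx(persistence, rel=0.2)


class TestSuperplotFigure:
    def test_figure_renders(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from vesiquant.migration import superplot_figure

        df = TestSuperplot.cohort({"ctrl": 0.40, "kd": 0.32}, seed=1)
        ax = superplot_figure(df, "average_speed")
        assert len(ax.collections) > 0
        out = tmp_path / "superplot.png"
        ax.figure.savefig(out)
        assert out.stat().st_size > 0
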
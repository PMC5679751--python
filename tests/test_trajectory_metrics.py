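"""Trajectory metrics: alignment, windowing, per-cell statistics, rose plots.

The naive oracle recomputes every metric directly from raw (t, x, y) rows
with plain Python arithmetic, independently of the pipeline's vectorized
path.
"""

import math

import numpy as np
import pytest

from gastrotrack.embryo_geometry import DirectionConvention
from gastrotrack.synthetic_embryo import SimulationParams, simulate_tracks
from gastrotrack.track_io import Track, TrackSet
from gastrotrack.trajectory_metrics import (
    WindowedSegment,
    align_at_onset,
    bin_into_windows,
    compute_window_metrics,
    metrics_to_frame,
    net_displacement,
    path_length,
    rose_histogram,
    speed,
    straightness,
    summarize_by_genotype,
)


def seg(points, w=1):
    pts = np.asarray(points, float)
    return WindowedSegment(
        track_id="t", window_index=w, t=pts[:, 0], xy=pts[:, 1:],
        window_start=float(pts[0, 0]), window_end=float(pts[-1, 0]) + 1,
    )


# -- naive oracle -----------------------------------------------------------

def naive_path(rows):
    return sum(
        math.hypot(b[1] - a[1], b[2] - a[2]) for a, b in zip(rows, rows[1:])
    )


def naive_net(rows):
    return math.hypot(rows[-1][1] - rows[0][1], rows[-1][2] - rows[0][2])


def naive_rose_weights(rows, n_bins=8):
    """Bins centered on compass directions; +x dorsal = 0, ccw."""
    w = [0.0] * n_bins
    width = 360.0 / n_bins
    for a, b in zip(rows, rows[1:]):
        dx, dy = b[1] - a[1], b[2] - a[2]
        mag = math.hypot(dx, dy)
        if mag == 0:
            continue
        ang = math.degrees(math.atan2(dy, dx)) % 360.0
        w[int(((ang + width / 2) % 360.0) // width)] += mag
    return w


class TestAlignment:
    def make_ts(self, onset=30.0):
        tr = Track("a", t=[0, 25, 50, 75], xy=[[0, 0], [1, 0], [2, 0], [3, 0]])
        return TrackSet("e", "wt", [tr], internalization_onset=onset,
                        frame_interval=25)

    def test_onset_becomes_zero(self):
        ts = align_at_onset(self.make_ts(30.0))
        assert np.allclose(ts.tracks[0].t, [-30, -5, 20, 45])
        assert ts.internalization_onset == 0.0

    def test_two_embryos_align_to_common_origin(self):
        a = align_at_onset(self.make_ts(25.0))
        b = align_at_onset(self.make_ts(50.0))
        assert 0.0 in a.tracks[0].t and 0.0 in b.tracks[0].t

    def test_onset_unset_or_too_late(self):
        with pytest.raises(ValueError, match="unset"):
            align_at_onset(self.make_ts(None))
        with pytest.raises(ValueError, match="onset"):
            align_at_onset(self.make_ts(100.0))


class TestWindowing:
    def test_equal_boundaries_180_min(self):
        # a 180-min span in four windows cuts at 45-min boundaries
        tr = Track("a", t=np.arange(0, 181, 5),
                   xy=np.zeros((37, 2)) + np.arange(37)[:, None])
        ts = TrackSet("e", "wt", [tr], internalization_onset=0.0,
                      frame_interval=5)
        segs = bin_into_windows(ts, 4)
        starts = sorted(s.window_start for s in segs)
        assert starts == [0.0, 45.0, 90.0, 135.0]

    def test_boundary_point_goes_to_later_window(self):
        tr = Track("a", t=[0, 45, 46, 90, 180], xy=np.zeros((5, 2)))
        ts = TrackSet("e", "wt", [tr], internalization_onset=0.0)
        segs = {s.window_index: s for s in bin_into_windows(ts, 4)}
        assert 45.0 in segs[1].t and 45.0 not in segs[0].t
        # final boundary (t = T) is closed into the last window
        assert 180.0 in segs[3].t

    def test_pre_onset_points_excluded(self):
        tr = Track("a", t=[-10, 0, 50, 100], xy=np.zeros((4, 2)))
        ts = TrackSet("e", "wt", [tr], internalization_onset=0.0)
        segs = bin_into_windows(ts, 2)
        assert all((s.t >= 0).all() for s in segs)

    def test_invalid_window_count(self, small_params):
        ts = simulate_tracks(small_params)
        with pytest.raises(ValueError):
            bin_into_windows(ts, 0)

    def test_four_point_segment_excluded_from_metrics(self):
        # five points in windows 1-3 but only four in window 2 -> no metrics there
        t = np.array([50.0, 52, 54, 56])  # inside [45, 90) only
        tr = Track("a", t=t, xy=np.cumsum(np.ones((4, 2)), axis=0))
        ts = TrackSet("e", "wt", [tr], internalization_onset=0.0)
        m = compute_window_metrics(ts, 4, span=180.0)
        assert m == []

    def test_first_window_excluded_by_default(self):
        t = np.arange(0, 181, 2.0)
        tr = Track("a", t=t, xy=np.cumsum(np.ones((t.size, 2)), axis=0))
        ts = TrackSet("e", "wt", [tr], internalization_onset=0.0)
        m = compute_window_metrics(ts, 4)
        assert sorted({x.window_index for x in m}) == [1, 2, 3]
        m_all = compute_window_metrics(ts, 4, exclude_first_window=False)
        assert sorted({x.window_index for x in m_all}) == [0, 1, 2, 3]


class TestPerSegmentMetrics:
    RIGHT_ANGLE = [[0, 0, 0], [1, 1, 0], [2, 1, 1]]  # (t, x, y)

    def test_hand_oracles_right_angle_path(self):
        s = seg(self.RIGHT_ANGLE)
        assert path_length(s) == pytest.approx(2.0)
        assert net_displacement(s) == pytest.approx(math.sqrt(2))
        assert straightness(s) == pytest.approx(math.sqrt(2) / 2)
        assert speed(s) == pytest.approx(1.0)  # 2 um over 2 min

    def test_straight_track_straightness_one(self):
        s = seg([[0, 0, 0], [1, 2, 0], [2, 4, 0], [3, 6, 0]])
        assert straightness(s) == 1.0
        assert path_length(s) == net_displacement(s)

    def test_closed_loop_straightness_zero(self):
        s = seg([[0, 0, 0], [1, 1, 0], [2, 1, 1], [3, 0, 1], [4, 0, 0]])
        assert net_displacement(s) == 0.0
        assert straightness(s) == 0.0

    def test_stationary_cell(self):
        s = seg([[0, 5, 5], [10, 5, 5]])
        assert path_length(s) == 0.0
        assert speed(s) == 0.0
        with pytest.raises(ValueError):
            straightness(s)

    def test_speed_is_path_based(self):
        # zigzag: 20 um path over 10 min -> 2 um/min regardless of net
        s = seg([[0, 0, 0], [5, 10, 0], [10, 0, 0]])
        assert speed(s) == pytest.approx(2.0)
        assert net_displacement(s) == 0.0

    def test_reciprocal_straightness(self):
        s = seg(self.RIGHT_ANGLE)
        assert straightness(s, reciprocal=True) == pytest.approx(math.sqrt(2))

    def test_too_few_points_rejected(self):
        s = seg([[0, 0, 0]])
        for fn in (path_length, net_displacement, speed):
            with pytest.raises(ValueError):
                fn(s)

    def test_net_le_path_on_random_segments(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 30)
            pts = np.column_stack([np.arange(n), rng.normal(size=(n, 2))])
            s = seg(pts)
            assert net_displacement(s) <= path_length(s) + 1e-12


class TestRoseHistogram:
    def test_single_direction_fills_one_bin(self, geom, conv):
        s = seg([[i, 0, float(i)] for i in range(6)])  # straight animal-ward
        rose = rose_histogram([s], geom, conv)
        assert rose.proportion_toward("animal", conv) == pytest.approx(1.0)
        assert rose.proportions.sum() == pytest.approx(1.0)

    def test_opposite_equal_steps_split_half_half(self, geom, conv):
        up = seg([[i, 0, 2.0 * i] for i in range(6)])
        down = seg([[i, 0, -2.0 * i] for i in range(6)])
        rose = rose_histogram([up, down], geom, conv)
        assert rose.proportion_toward("animal", conv) == pytest.approx(0.5)
        assert rose.proportion_toward("vegetal", conv) == pytest.approx(0.5)
        assert rose.n_cells == 2

    def test_zero_steps_skipped(self, geom, conv):
        s = seg([[0, 0, 0], [1, 0, 0], [2, 0, 1], [3, 0, 2], [4, 0, 3]])
        rose = rose_histogram([s], geom, conv)
        assert rose.proportion_toward("animal", conv) == pytest.approx(1.0)

    def test_short_segments_filtered(self, geom, conv):
        s = seg([[0, 0, 0], [1, 0, 1]])  # 2 points < 5
        with pytest.raises(ValueError, match="qualifying"):
            rose_histogram([s], geom, conv)

    def test_additivity_before_normalization(self, geom, conv):
        rng = np.random.default_rng(5)
        segs = [
            seg(np.column_stack([np.arange(8), rng.normal(size=(8, 2))]))
            for _ in range(10)
        ]
        whole = rose_histogram(segs, geom, conv)
        part1 = rose_histogram(segs[:4], geom, conv)
        part2 = rose_histogram(segs[4:], geom, conv)
        assert np.allclose(whole.weights, part1.weights + part2.weights)

    def test_matches_naive_oracle(self, geom, conv):
        rng = np.random.default_rng(9)
        pts = np.column_stack([np.arange(30), rng.normal(0, 3, (30, 2))])
        s = seg(pts)
        rose = rose_histogram([s], geom, conv)
        naive = naive_rose_weights([tuple(r) for r in pts])
        # naive bin 0 is centered on +x = dorsal = angle 0 under defaults
        assert np.allclose(rose.weights, naive, atol=1e-9)


class TestPipelineAgainstNaive:
    def test_100_random_tracks_match_to_1e9(self, geom, conv):
        """Independent plain-Python recomputation agrees with the pipeline."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(5, 40)
            t = np.arange(n) * 2.0
            xy = np.cumsum(rng.normal(0.2, 1.5, (n, 2)), axis=0)
            s = WindowedSegment("t", 1, t, xy, 0.0, float(t[-1]))
            rows = [(t[i], xy[i, 0], xy[i, 1]) for i in range(n)]
            assert path_length(s) == pytest.approx(naive_path(rows), abs=1e-9)
            assert net_displacement(s) == pytest.approx(naive_net(rows), abs=1e-9)
            assert straightness(s) == pytest.approx(
                naive_net(rows) / naive_path(rows), abs=1e-9
            )
            assert speed(s) == pytest.approx(
                naive_path(rows) / (rows[-1][0] - rows[0][0]), abs=1e-9
            )
            rose = rose_histogram([s], geom, conv)
            assert np.allclose(rose.weights, naive_rose_weights(rows), atol=1e-9)


class TestRigidInvariance:
    def test_metrics_invariant_under_rotation_translation(self, conv):
        from gastrotrack.embryo_geometry import EmbryoGeometry
        from conftest import rigid_transform

        rng = np.random.default_rng(77)
        n = 20
        t = np.arange(n) * 2.0
        xy = np.cumsum(rng.normal(0.3, 1.0, (n, 2)), axis=0)
        geom = EmbryoGeometry([0, 600], [0, 0], [300, 300], 600, 600)
        s = WindowedSegment("t", 1, t, xy, 0.0, t[-1])
        ref = (path_length(s), net_displacement(s), straightness(s), speed(s))
        rose_ref = rose_histogram([s], geom, conv).proportions
        for _ in range(5):
            R, tv = rigid_transform(rng)
            g2 = EmbryoGeometry(
                R @ np.array([0.0, 600]) + tv, R @ np.array([0.0, 0]) + tv,
                R @ np.array([300.0, 300]) + tv, 600, 600,
            )
            s2 = WindowedSegment("t", 1, t, xy @ R.T + tv, 0.0, t[-1])
            got = (path_length(s2), net_displacement(s2), straightness(s2),
                   speed(s2))
            assert np.allclose(got, ref, atol=1e-9)
            assert np.allclose(
                rose_histogram([s2], g2, conv).proportions, rose_ref, atol=1e-9
            )


class TestGenotypeSummary:
    def test_single_cell_group_flagged(self):
        import pandas as pd

        frame = pd.DataFrame(
            [{"embryo_id": "e", "genotype": "wt", "track_id": "a", "window": 1,
              "n_points": 5, "path_length_um": 2, "net_displacement_um": 1,
              "straightness": 0.5, "speed_um_min": 1.0}]
        )
        out = summarize_by_genotype(frame)
        assert out.loc[0, "speed_mean"] == 1.0
        assert out.loc[0, "straightness_sem"] == 0.0
        assert not out.loc[0, "sem_defined"]

    def test_duplicated_cohort_symmetric(self, small_params):
        ts = simulate_tracks(small_params)
        m = compute_window_metrics(ts, 4)
        f1 = metrics_to_frame(m, embryo_id="e1", genotype="g1")
        f2 = metrics_to_frame(m, embryo_id="e2", genotype="g2")
        import pandas as pd

        out = summarize_by_genotype(pd.concat([f1, f2]))
        g1 = out[out.genotype == "g1"].drop(columns="genotype").reset_index(drop=True)
        g2 = out[out.genotype == "g2"].drop(columns="genotype").reset_index(drop=True)
        pd.testing.assert_frame_equal(g1, g2)

    def test_slow_vs_fast_cohorts_recovered(self):
        """Simulated cohorts with mean speeds ~1 and ~2 um/min separate."""
        import pandas as pd
        from gastrotrack.synthetic_embryo import expected_speed, params_for

        frames = []
        for gt, sigma in (("slow", 1.5958), ("fast", 3.1915)):
            # pure-noise walks: Rayleigh mean sigma*sqrt(pi/2) per 2-min step
            p = SimulationParams(
                n_cells=100, duration=120, drift_animal=0.0,
                noise_sigma=sigma, division_prob_per_window=0,
                death_prob_per_window=0, seed=5,
            )
            ts = simulate_tracks(p, genotype=gt)
            m = compute_window_metrics(ts, 4)
            frames.append(metrics_to_frame(m, embryo_id=gt, genotype=gt))
            exp = expected_speed(p)
            assert exp == pytest.approx(sigma * math.sqrt(math.pi / 2) / 2)
        out = summarize_by_genotype(pd.concat(frames))
        for gt, target in (("slow", 1.0), ("fast", 2.0)):
            grp = out[out.genotype == gt]
            mean = np.average(grp.speed_mean, weights=grp.n_cells)
            sem = grp.speed_sem.max()
            assert abs(mean - target) < 3 * sem
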
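import numpy as np
import pytest

from wavetraj.segmentation import (
    ACTIVE,
    EXCLUDED,
    PASSIVE,
    ActiveDetectionParams,
    ActiveLabels,
    classify_active,
    extract_runs,
    merge_runs_to_flights,
    noise_sigma2,
    percent_time_active,
    turning_angles,
    universal_threshold,
)
from wavetraj.synthgen import SimConfig, simulate_brownian, simulate_stop_and_go
from wavetraj.wavelet import WaveletMap, cwt_trajectory

from conftest import make_traj


def _map_from_row(row, scale=2):
    row = np.asarray(row, dtype=float)[None, :]
    return WaveletMap(
        track_id="m", axis="x", scales=np.array([scale]), C=row,
        edge=np.zeros_like(row, dtype=bool),
    )


class TestNoiseSigma2:
    def test_mad_formula_identity(self):
        assert noise_sigma2(_map_from_row([0.6745, -0.6745] * 10)) == pytest.approx(1.0)

    def test_all_zero_row_gives_zero(self):
        assert noise_sigma2(_map_from_row(np.zeros(20))) == 0.0

    def test_consistent_for_gaussian_noise(self, rng):
        # scale-2 coefficient of i.i.d. noise is a difference of two samples:
        # its standard deviation is sigma * sqrt(2)
        from wavetraj.wavelet import cwt_series

        sigma = 0.05
        m = cwt_series(rng.normal(0, sigma, 10_000), scales=[2])
        assert noise_sigma2(m) == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_missing_scale_two_raises(self):
        with pytest.raises(ValueError, match="scale 2"):
            noise_sigma2(_map_from_row(np.zeros(10), scale=5))


class TestUniversalThreshold:
    def test_hand_computed_value(self):
        p = ActiveDetectionParams(a_tilde=20, r=1.0)
        expected = np.sqrt(2.0 * np.log(100.0)) * np.sqrt(10.0)  # = 9.59704...
        assert universal_threshold(1.0, 100, p) == pytest.approx(expected, abs=1e-9)

    def test_zero_noise_gives_zero_threshold(self):
        assert universal_threshold(0.0, 100, ActiveDetectionParams()) == 0.0

    def test_proportional_in_r_and_monotone_in_n_and_scale(self):
        p1 = ActiveDetectionParams(r=0.8)
        p2 = ActiveDetectionParams(r=1.6)
        assert universal_threshold(1.0, 100, p2) == pytest.approx(
            2 * universal_threshold(1.0, 100, p1))
        assert universal_threshold(1.0, 200, p1) > universal_threshold(1.0, 100, p1)
        assert universal_threshold(1.0, 100, ActiveDetectionParams(a_tilde=40)) > \
            universal_threshold(1.0, 100, ActiveDetectionParams(a_tilde=20))

    def test_degenerate_n_raises(self):
        with pytest.raises(ValueError):
            universal_threshold(1.0, 1, ActiveDetectionParams())


class TestClassifyActive:
    def test_noiseless_ballistic_track_fully_active(self):
        t = np.arange(200) * 0.2
        tr = make_traj(0.5 * t / np.sqrt(2), 0.5 * t / np.sqrt(2))
        labels = classify_active(*cwt_trajectory(tr))
        ne = labels.params.n_exclude
        assert np.all(labels.states[:ne] == EXCLUDED)
        assert np.all(labels.states[-ne:] == EXCLUDED)
        assert np.all(labels.states[ne:-ne] == ACTIVE)

    def test_pure_localization_noise_rarely_flagged(self, rng):
        frac = []
        for _ in range(5):
            tr = make_traj(rng.normal(0, 0.03, 1000), rng.normal(0, 0.03, 1000))
            lb = classify_active(*cwt_trajectory(tr))
            frac.append(lb.n_active / lb.n_valid)
        assert np.mean(frac) < 0.05

    def test_tethered_diffusion_false_positive_fraction_low(self):
        rng = np.random.default_rng(11)
        cfg = SimConfig()
        na = nv = 0
        for _ in range(10):
            lb = classify_active(*cwt_trajectory(simulate_brownian(cfg, rng=rng)))
            na, nv = na + lb.n_active, nv + lb.n_valid
        assert na / nv <= 0.05

    def test_planted_runs_recovered(self):
        rng = np.random.default_rng(7)
        cfg = SimConfig()
        hits = total = 0
        for _ in range(10):
            tr, gt = simulate_stop_and_go(cfg, rng=rng)
            runs = extract_runs(classify_active(*cwt_trajectory(tr)), tr)
            intervals = [(r.start_idx, r.end_idx) for r in runs]
            for s, e in gt.runs:
                total += 1
                hits += any(not (e < ds or s > de) for ds, de in intervals)
        assert total > 50
        assert hits / total >= 0.8

    def test_excluded_count_is_twice_half_detection_scale(self, rng):
        tr = make_traj(rng.normal(0, 0.03, 300), rng.normal(0, 0.03, 300))
        lb = classify_active(*cwt_trajectory(tr))
        assert np.sum(lb.states == EXCLUDED) == 2 * (lb.params.a_tilde // 2)


def _labels(states):
    return ActiveLabels(track_id="t", states=np.asarray(states, dtype=np.int8),
                        params=ActiveDetectionParams())


class TestExtractRuns:
    def test_straight_active_stretch_has_chord_length_and_zero_width(self):
        x = np.concatenate([np.zeros(5), np.linspace(0, 2, 10), np.full(5, 2.0)])
        states = np.array([PASSIVE] * 5 + [ACTIVE] * 10 + [PASSIVE] * 5)
        runs = extract_runs(_labels(states), make_traj(x))
        assert len(runs) == 1
        assert runs[0].l == pytest.approx(2.0)
        assert runs[0].w_max == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_run_width_is_corner_chord_distance(self):
        # legs (0,0)->(1,0)->(1,1): chord sqrt(2), corner at distance 1/sqrt(2)
        x = np.array([0.0, 0.5, 1.0, 1.0, 1.0])
        y = np.array([0.0, 0.0, 0.0, 0.5, 1.0])
        runs = extract_runs(_labels([ACTIVE] * 5), make_traj(x, y))
        assert runs[0].l == pytest.approx(np.sqrt(2.0))
        assert runs[0].w_max == pytest.approx(1.0 / np.sqrt(2.0))

    def test_no_active_points_gives_empty_list(self):
        assert extract_runs(_labels([PASSIVE] * 10), make_traj(np.zeros(10))) == []

    def test_single_active_point_has_no_chord_and_is_dropped(self):
        states = [PASSIVE] * 4 + [ACTIVE] + [PASSIVE] * 5
        assert extract_runs(_labels(states), make_traj(np.arange(10.0))) == []


class TestMergeRunsToFlights:
    def _run_fixture(self, segs):
        """Build a trajectory visiting straight segments, each marked active."""
        xs, ys, states = [], [], []
        for (x0, y0, x1, y1, active, n) in segs:
            xs.append(np.linspace(x0, x1, n))
            ys.append(np.linspace(y0, y1, n))
            states += [ACTIVE if active else PASSIVE] * n
        tr = make_traj(np.concatenate(xs), np.concatenate(ys))
        runs = extract_runs(_labels(states), tr)
        return runs, tr

    def test_collinear_runs_merge_into_one_flight(self):
        runs, tr = self._run_fixture([
            (0, 0, 1, 0, True, 6), (1, 0, 1.2, 0, False, 4), (1.2, 0, 3, 0, True, 6),
        ])
        assert len(runs) == 2
        flights = merge_runs_to_flights(runs, tr)
        assert len(flights) == 1
        assert flights[0].L == pytest.approx(3.0)

    def test_sharp_reversal_not_merged(self):
        # second run turns back by ~150 degrees
        runs, tr = self._run_fixture([
            (0, 0, 2, 0, True, 8), (2, 0, 2.1, 0, False, 3),
            (2.1, 0, 0.4, 1.0, True, 8),
        ])
        assert len(runs) == 2
        flights = merge_runs_to_flights(runs, tr)
        assert len(flights) == 2

    def test_lateral_offset_outside_corridor_not_merged(self):
        # straight first run (corridor floor 0.4 um), second run offset 1 um sideways
        runs, tr = self._run_fixture([
            (0, 0, 2, 0, True, 8), (2, 0, 2.5, 1.0, False, 3),
            (2.5, 1.0, 4.5, 1.0, True, 8),
        ])
        flights = merge_runs_to_flights(runs, tr)
        assert len(flights) == 2

    def test_every_run_in_exactly_one_flight(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(n_steps=800)
        for _ in range(5):
            tr, _ = simulate_stop_and_go(cfg, rng=rng)
            runs = extract_runs(classify_active(*cwt_trajectory(tr)), tr)
            flights = merge_runs_to_flights(runs, tr)
            member = [r for f in flights for r in f.runs]
            assert len(member) == len(runs)
            assert len({id(r) for r in member}) == len(runs)

    def test_flight_count_monotone_in_corridor_width(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(n_steps=1000)
        counts = {0.8: 0, 1.27: 0, 2.0: 0}
        for _ in range(10):
            tr, _ = simulate_stop_and_go(cfg, rng=rng)
            runs = extract_runs(classify_active(*cwt_trajectory(tr)), tr)
            for f in counts:
                counts[f] += len(merge_runs_to_flights(runs, tr, corridor_factor=f))
        assert counts[2.0] <= counts[1.27] <= counts[0.8]


class TestSummaries:
    def test_percent_time_active_arithmetic(self):
        half = _labels([EXCLUDED] * 2 + [ACTIVE] * 30 + [PASSIVE] * 30 + [EXCLUDED] * 2)
        assert percent_time_active([half]) == pytest.approx(50.0)
        assert percent_time_active([_labels([ACTIVE] * 10)]) == 100.0
        assert percent_time_active([_labels([PASSIVE] * 10)]) == 0.0

    def test_percent_time_active_requires_valid_points(self):
        with pytest.raises(ValueError):
            percent_time_active([_labels([EXCLUDED] * 4)])

    def test_turning_angles_for_canonical_geometries(self):
        def run(p0, p1):
            from wavetraj.segmentation import RunSegment

            return RunSegment("t", 0, 1, np.array(p0, float), np.array(p1, float),
                              l=1.0, duration=0.2, w_max=0.0)

        same = [run((0, 0), (1, 0)), run((2, 0), (3, 0))]
        reverse = [run((0, 0), (1, 0)), run((1, 0), (0, 0))]
        perp = [run((0, 0), (1, 0)), run((1, 0), (1, 1))]
        angles = turning_angles([same, reverse, perp])
        assert angles == pytest.approx([0.0, 180.0, 90.0])
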
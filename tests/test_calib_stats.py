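import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from cedphantom import (
    SegmentationParams,
    Trajectory,
    TrajectoryPoint,
    calibrate_segmentation,
    filter_noise,
    fit_mixed_model,
    get_preset,
    make_photo_series,
    make_trajectories,
    match_diffusion,
    percent_error,
    pooled_t_test,
    slope_through_origin,
    threshold_as_percent,
)
from cedphantom.calib_stats import trajectory_slope
from cedphantom.errors import (
    CalibrationError,
    FitError,
    RangeError,
    ValidationError,
)

MTL_NHP = [221.1, 212.2, 285.3, 204.7]
MTL_GEL = [196.7, 229.2, 260.2, 220.7, 207.0]


def make_traj(pairs, trial_id="t", group="agar", region="cortical"):
    points = tuple(
        TrajectoryPoint(float(i), float(x), float(y)) for i, (x, y) in enumerate(pairs)
    )
    return Trajectory(trial_id, group, region, points)


class TestSlopeThroughOrigin:
    def test_exact_proportionality(self):
        assert slope_through_origin([(1, 3), (2, 6)]) == pytest.approx(3.0)

    def test_closed_form(self):
        # sum(xy)/sum(x^2) = (2 + 10)/(1 + 4)
        assert slope_through_origin([(1, 2), (2, 5)]) == pytest.approx(12 / 5)

    def test_origin_only_undefined(self):
        with pytest.raises(FitError):
            slope_through_origin([(0, 0)])

    def test_nan_measurements_ignored(self):
        assert slope_through_origin([(1, 3), (2, np.nan)]) == pytest.approx(3.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 200), n=st.integers(1, 30))
    def test_matches_oracle_on_random_points(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 50, n)
        y = rng.uniform(0, 200, n)
        expected = float(np.sum(x * y) / np.sum(x * x))
        assert slope_through_origin(zip(x, y)) == pytest.approx(expected, rel=1e-13)


class TestFilterNoise:
    def test_proportional_data_unchanged(self):
        traj = make_traj([(x, 3 * x) for x in range(1, 11)])
        assert filter_noise(traj).points == traj.points

    def test_removes_clear_outlier(self):
        # 20 points on y=3x keep the pooled fit near 3; one point at 1.5x the line
        pairs = [(x, 3 * x) for x in range(1, 21)]
        pairs.insert(5, (5.0, 1.5 * 15.0))
        traj = make_traj(pairs)
        out = filter_noise(traj)
        assert len(out.points) == 20
        assert (5.0, 22.5) not in [(p.infused_ul, p.measured_ul) for p in out.points]

    def test_point_exactly_at_cutoff_retained(self):
        # fixed-point construction: iterate y -> 1.1 * fit_slope * x0 until the
        # suspect point sits exactly (to the float bit) at 1.1x the fitted line
        x0, y = 2.0, 6.0
        for _ in range(100):
            traj = make_traj([(1, 3), (2, 6), (x0, y), (3, 9)])
            y_new = 1.1 * trajectory_slope(traj) * x0
            if y_new == y:
                break
            y = y_new
        traj = make_traj([(1, 3), (2, 6), (x0, y), (3, 9)])
        assert y == 1.1 * trajectory_slope(traj) * x0  # converged to the cutoff
        assert len(filter_noise(traj).points) == 4

    def test_never_removes_points_below_line(self):
        rng = np.random.default_rng(5)
        pairs = [(x, 3 * x - abs(rng.normal(0, 2))) for x in np.linspace(1, 30, 25)]
        traj = make_traj([(x, max(y, 0)) for x, y in pairs])
        assert filter_noise(traj).points == traj.points

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(11)
        traj = make_traj(
            [(x, max(3 * x + rng.normal(0, 6), 0)) for x in np.linspace(1, 30, 25)]
        )
        assert set(filter_noise(traj).points) <= set(traj.points)


class TestMixedModel:
    def test_null_case_identical_slopes(self):
        agar, nhp = make_trajectories((4, 4), (3.0, 3.0), slope_sd=0, noise_sd=0, seed=0)
        fit = fit_mixed_model(agar, nhp)
        assert fit.base_slope == pytest.approx(3.0, abs=1e-6)
        assert fit.interaction == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_interaction(self):
        agar, nhp = make_trajectories(
            (10, 10), (3.0, 4.0), slope_sd=0.3, noise_sd=2.0, seed=20
        )
        fit = fit_mixed_model(agar, nhp)
        assert abs(fit.interaction - 1.0) <= 3 * fit.interaction_se

    def test_one_noiseless_trial_per_group(self):
        agar, nhp = make_trajectories((1, 1), (2.0, 5.0), slope_sd=0, noise_sd=0, seed=0)
        fit = fit_mixed_model(agar, nhp)
        assert fit.interaction == pytest.approx(3.0, abs=1e-6)

    def test_interaction_sign_follows_reference(self):
        agar, nhp = make_trajectories((5, 5), (3.0, 4.0), slope_sd=0, noise_sd=0, seed=1)
        assert fit_mixed_model(agar, nhp, reference="agar").interaction == pytest.approx(1.0, abs=1e-6)
        assert fit_mixed_model(agar, nhp, reference="nhp").interaction == pytest.approx(-1.0, abs=1e-6)

    def test_trial_slopes_reported_for_every_trial(self):
        agar, nhp = make_trajectories((3, 2), (3.0, 4.0), slope_sd=0.2, noise_sd=1.0, seed=2)
        fit = fit_mixed_model(agar, nhp)
        assert len(fit.trial_slopes) == 5

    def test_trial_slopes_track_generating_slopes(self):
        agar, nhp = make_trajectories((6, 6), (3.0, 4.0), slope_sd=0.4, noise_sd=0.5, seed=3)
        fit = fit_mixed_model(agar, nhp)
        for traj in agar + nhp:
            fitted = fit.trial_slopes[f"{traj.group}:{traj.trial_id}"]
            assert fitted == pytest.approx(trajectory_slope(traj), abs=0.15)

    def test_empty_group_rejected(self):
        agar, _ = make_trajectories((2, 1), (3.0, 3.0), seed=0)
        with pytest.raises(FitError):
            fit_mixed_model(agar, [])

    def test_interaction_bias_vanishes_as_noise_vanishes(self):
        biases = []
        for noise in (4.0, 1.0, 0.0):
            agar, nhp = make_trajectories(
                (8, 8), (3.0, 4.0), slope_sd=0.0, noise_sd=noise, n_points=30, seed=9
            )
            fit = fit_mixed_model(agar, nhp)
            biases.append(abs(fit.interaction - 1.0))
        assert biases[-1] == pytest.approx(0.0, abs=1e-6)
        assert biases[-1] <= biases[0] + 1e-9


class TestCalibration:
    def test_reference_equal_to_agar_gives_zero_objective(self, mtl):
        params = SegmentationParams(cut_row=60, scale=10.0)
        series = make_photo_series(mtl, 3.0, 1.0)
        frames = {"t1": [f for f, _ in series]}
        from cedphantom.photo_seg import segment_series

        reference_params = SegmentationParams(
            component="blue", threshold=200, cut_row=60, scale=10.0
        )
        ref = segment_series(frames["t1"], reference_params, mtl, trial_id="ref")
        ref_nhp = Trajectory("ref", "nhp", "mtl", ref.points)
        result = calibrate_segmentation(
            frames, mtl, [ref_nhp],
            components=["blue"], thresholds=[120, 200, 240], base_params=params,
        )
        assert result.threshold == 200
        assert result.objective == pytest.approx(0.0, abs=1e-9)

    def test_grid_of_one_point(self, mtl):
        params = SegmentationParams(cut_row=60, scale=10.0)
        series = make_photo_series(mtl, 3.0, 1.0)
        frames = {"t1": [f for f, _ in series]}
        _, nhp = make_trajectories((1, 2), (3.0, 3.0), slope_sd=0, noise_sd=0, seed=0, infused_max=15)
        result = calibrate_segmentation(
            frames, mtl, nhp, components=["blue"], thresholds=[220], base_params=params
        )
        assert (result.component, result.threshold) == ("blue", 220)
        assert result.objective >= 0

    def test_recovers_generator_slope(self, mtl):
        params = SegmentationParams(cut_row=60, scale=10.0)
        frames = {}
        for i, s in enumerate([2.9, 3.0, 3.1]):
            series = make_photo_series(mtl, s, 1.0)
            frames[f"t{i}"] = [f for f, _ in series]
        _, nhp = make_trajectories((1, 3), (3.0, 3.0), slope_sd=0, noise_sd=0, seed=0, infused_max=15)
        result = calibrate_segmentation(
            frames, mtl, nhp,
            components=["blue"], thresholds=range(120, 241, 20), base_params=params,
        )
        agar_slopes = [v for k, v in result.slope_table.items() if k.startswith("agar")]
        assert np.mean(agar_slopes) == pytest.approx(3.0, rel=0.05)

    def test_objective_minimal_over_grid(self, mtl):
        params = SegmentationParams(cut_row=60, scale=10.0)
        series = make_photo_series(mtl, 3.0, 1.0)
        frames = {"t1": [f for f, _ in series]}
        _, nhp = make_trajectories((1, 2), (2.5, 2.5), slope_sd=0, noise_sd=0, seed=0, infused_max=15)
        result = calibrate_segmentation(
            frames, mtl, nhp, components=["green", "blue"],
            thresholds=[140, 180, 220], base_params=params,
        )
        assert all(result.objective <= obj for _, _, obj in result.grid)

    def test_all_empty_grid_fails(self, mtl):
        params = SegmentationParams(cut_row=60, scale=10.0)
        series = make_photo_series(mtl, 3.0, 1.0)
        frames = {"t1": [f for f, _ in series]}
        _, nhp = make_trajectories((1, 1), (3.0, 3.0), slope_sd=0, noise_sd=0, seed=0)
        with pytest.raises(CalibrationError):
            calibrate_segmentation(
                frames, mtl, nhp, components=["red"], thresholds=[1], base_params=params
            )


class TestMatchDiffusion:
    def test_constant_at_reference(self):
        series = [[(t, 230.0) for t in range(0, 10, 2)] for _ in range(3)]
        m = match_diffusion(series, [230.0])
        assert m.t_star == 0.0 and m.percent_error == 0.0

    def test_table_values_percent_error(self):
        series = [[(29.0, v)] for v in MTL_GEL]
        m = match_diffusion(series, MTL_NHP, tolerance=5.0)
        assert m.t_star == 29.0
        assert round(m.percent_error, 1) == 3.5

    def test_analytic_crossing_time(self):
        # v(t) = 260 - 130 e^(-t/tau) crosses 230 at tau ln(130/30)
        tau, ref = 8.0, 230.0
        times = np.arange(0.0, 40.0, 0.5)
        series = [[(t, 260 - 130 * np.exp(-t / tau)) for t in times]] * 2
        m = match_diffusion(series, [ref], tolerance=0.01)
        analytic = tau * np.log(130 / 30)
        assert abs(m.t_star - analytic) <= 0.5

    def test_median_smoothing_ignores_spike(self):
        times = list(range(10))
        clean = [(t, 230.0) for t in times]
        spiky = [(t, 230.0 if t != 4 else 500.0) for t in times]
        m = match_diffusion([clean, spiky], [230.0], tolerance=1.0)
        assert m.percent_error == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_time_support_rejected(self):
        with pytest.raises(ValidationError):
            match_diffusion([[(0, 1.0)], [(5, 1.0)]], [1.0])


class TestScalarStats:
    def test_table_means_percent_error(self):
        assert round(percent_error(np.mean(MTL_NHP), np.mean(MTL_GEL)), 1) == 3.5

    def test_equal_means_zero(self):
        assert percent_error(100.0, 100.0) == 0.0

    def test_ten_percent(self):
        assert percent_error(100.0, 90.0) == pytest.approx(10.0)

    def test_scale_invariance(self):
        assert percent_error(123.0, 77.0) == pytest.approx(percent_error(12.3, 7.7))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_error(0.0, 5.0)

    def test_published_pooling_t_test(self):
        assert round(pooled_t_test(MTL_NHP[:2], MTL_NHP[2:]), 2) == 0.56

    def test_identical_groups_p_one(self):
        assert pooled_t_test([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_p_matches_t_density_quadrature(self):
        a, b = [1.0, 2.5, 3.1], [2.0, 4.0, 5.5, 3.3]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t), np.inf)
        assert pooled_t_test(a, b) == pytest.approx(2 * tail, rel=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            pooled_t_test([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("threshold,percent", [(110, 43), (67, 26), (100, 39), (0, 0), (255, 100)])
    def test_threshold_as_percent(self, threshold, percent):
        assert threshold_as_percent(threshold) == percent

    def test_threshold_percent_out_of_range(self):
        with pytest.raises(RangeError):
            threshold_as_percent(256)


class TestTrajectoryValidation:
    def test_decreasing_infused_rejected(self):
        with pytest.raises(ValidationError):
            make_traj([(5, 10), (3, 12)])

    def test_negative_measured_rejected(self):
        with pytest.raises(ValidationError):
            make_traj([(5, -1)])

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            make_traj([(1, 3)], group="mouse")
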
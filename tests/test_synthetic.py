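"""Generator ground truth: motion models, renderer, rheology synthesis."""

import numpy as np
import pytest

from gelscope import synthetic as syn
from gelscope.exceptions import ConfigurationError, ParameterError
from gelscope.fitting import fit_power_law
from gelscope.rheology import loss_tangent
from gelscope.synthetic import MotionModel, OpticsModel, TrajectoryEnsemble


class TestMotionModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="brownian"),  # missing D
            dict(kind="brownian", diffusion_coefficient=-1.0),
            dict(kind="brownian", diffusion_coefficient=0.1, hurst_exponent=0.5),
            dict(kind="fbm", hurst_exponent=0.5),  # missing coefficient
            dict(kind="fbm", diffusion_coefficient=0.1, hurst_exponent=1.5),
            dict(kind="trapped", trap_stiffness=-1.0, noise_scale=0.1),
            dict(kind="levy"),
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MotionModel(**kwargs)

    def test_error_names_the_field(self):
        with pytest.raises(ParameterError, match="diffusion_coefficient"):
            MotionModel(kind="brownian")


class TestTrajectories:
    def test_zero_diffusivity_is_exactly_static(self):
        traj = syn.simulate_trajectories(
            MotionModel.brownian(0.0), 20, 50, 0.02, (10, 10), seed=1
        )
        assert np.all(traj.unwrapped == traj.unwrapped[:, :1, :])

    def test_brownian_msd_matches_closed_form(self):
        # <r^2>(0.1 s) = 4 * D * dt = 0.16 um^2 for D = 0.4
        traj = syn.simulate_trajectories(
            MotionModel.brownian(0.4), 500, 500, 0.02, (25.6, 25.6), seed=1
        )
        _, msd = traj.ensemble_msd([5])
        assert msd[0] == pytest.approx(0.16, rel=0.05)

    @pytest.mark.parametrize("d", [0.1, 0.4, 1.0])
    def test_brownian_msd_loglog_slope_is_unity(self, d):
        traj = syn.simulate_trajectories(
            MotionModel.brownian(d), 400, 300, 0.02, (25.6, 25.6), seed=3
        )
        lags, msd = traj.ensemble_msd([1, 2, 4, 8, 16, 32, 64])
        slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
        assert 0.95 <= slope <= 1.05

    @pytest.mark.parametrize("hurst", [1 / 6, 1 / 4, 1 / 2])
    def test_fbm_msd_slope_is_2h(self, hurst):
        traj = syn.simulate_trajectories(
            MotionModel.fbm(hurst, 0.05), 400, 300, 0.02, (25.6, 25.6), seed=4
        )
        lags, msd = traj.ensemble_msd([1, 2, 4, 8, 16, 32, 64])
        slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
        assert slope == pytest.approx(2 * hurst, abs=0.05)

    def test_fbm_msd_matches_closed_form_amplitude(self):
        # MSD = 4 * D_alpha * dt^(2H), the analytic oracle for the
        # exact-covariance synthesis.
        traj = syn.simulate_trajectories(
            MotionModel.fbm(1 / 4, 0.05), 600, 200, 0.02, (25.6, 25.6), seed=5
        )
        lags, msd = traj.ensemble_msd([2, 8, 32])
        expected = 4 * 0.05 * lags ** 0.5
        assert np.allclose(msd, expected, rtol=0.08)

    def test_davies_harte_branch_matches_closed_form(self):
        # > 2048 steps exercises the circulant-embedding path.
        traj = syn.simulate_trajectories(
            MotionModel.fbm(1 / 3, 0.05), 40, 2300, 0.02, (50, 50), seed=6
        )
        lags, msd = traj.ensemble_msd([4, 16, 64, 256])
        expected = 4 * 0.05 * lags ** (2 / 3)
        assert np.allclose(msd, expected, rtol=0.10)

    def test_trapped_msd_plateaus(self):
        k, d = 50.0, 0.01
        traj = syn.simulate_trajectories(
            MotionModel.trapped(k, d), 500, 400, 0.02, (25.6, 25.6), seed=7
        )
        lags, msd = traj.ensemble_msd([50, 100, 200])
        assert np.allclose(msd, 4 * d / k, rtol=0.10)

    def test_wrapped_coordinates_stay_in_box(self):
        traj = syn.simulate_trajectories(
            MotionModel.brownian(2.0), 50, 200, 0.02, (5.0, 5.0), seed=8
        )
        assert traj.positions.min() >= 0
        assert traj.positions.max() < 5.0

    def test_seed_determinism(self):
        a = syn.simulate_trajectories(MotionModel.brownian(0.4), 30, 40, 0.02, (10, 10), 9)
        b = syn.simulate_trajectories(MotionModel.brownian(0.4), 30, 40, 0.02, (10, 10), 9)
        assert np.array_equal(a.unwrapped, b.unwrapped)


def _single_particle_traj(positions_um, box=(12.8, 12.8)):
    arr = np.asarray(positions_um, dtype=float)[None, :, :]
    return TrajectoryEnsemble(arr, arr.copy(), 0.02, box, seed=0)


class TestRenderer:
    def test_static_scene_renders_identically(self):
        traj = _single_particle_traj([[6.4, 6.4], [6.4, 6.4], [6.4, 6.4]])
        optics = OpticsModel(image_shape=(64, 64), read_noise_sigma=0.0, shot_noise=False)
        stack = syn.render_movie(traj, optics, seed=0)
        assert np.array_equal(stack.frames[0], stack.frames[1])
        assert np.array_equal(stack.frames[0], stack.frames[2])

    def test_empty_ensemble_is_pure_background(self):
        traj = TrajectoryEnsemble(
            np.zeros((0, 3, 2)), np.zeros((0, 3, 2)), 0.02, (6.4, 6.4), seed=0
        )
        optics = OpticsModel(
            image_shape=(64, 64), background=100.0, read_noise_sigma=0.0, shot_noise=False
        )
        stack = syn.render_movie(traj, optics, seed=0)
        assert np.all(stack.frames == 100)

    def test_subpixel_centroid_displacement(self):
        # 3.0 px shift in x between frames -> centroid moves 3.0 px.
        traj = _single_particle_traj([[3.20, 3.20], [3.50, 3.20]], box=(6.4, 6.4))
        optics = OpticsModel(
            image_shape=(64, 64), background=0.0, read_noise_sigma=0.0, shot_noise=False
        )
        stack = syn.render_movie(traj, optics, seed=0)
        cols = np.arange(64)

        def centroid_x(img):
            return float((img.sum(axis=0) * cols).sum() / img.sum())

        dx = centroid_x(stack.frames[1].astype(float)) - centroid_x(
            stack.frames[0].astype(float)
        )
        assert dx == pytest.approx(3.0, abs=0.05)

    def test_renderer_is_linear_in_the_ensemble(self):
        rng = np.random.default_rng(0)
        pos_a = rng.uniform(1, 5, (4, 2, 2))
        pos_b = rng.uniform(1, 5, (3, 2, 2))
        optics = OpticsModel(
            image_shape=(64, 64), background=50.0, read_noise_sigma=0.0, shot_noise=False
        )

        def render(pos):
            traj = TrajectoryEnsemble(pos, pos.copy(), 0.02, (6.4, 6.4), seed=0)
            return syn.render_movie(traj, optics, seed=0).frames.astype(float)

        combined = render(np.concatenate([pos_a, pos_b]))
        separate = render(pos_a) + render(pos_b) - 50.0
        # Quantization rounds each movie independently: at most 1 count apart.
        assert np.max(np.abs(combined - separate)) <= 1.0

    def test_clipping_is_warned_and_counted(self):
        # Two coincident spots push the summed peak past the 8-bit ceiling.
        pos = np.array([[[3.2, 3.2], [3.2, 3.2]], [[3.2, 3.2], [3.2, 3.2]]])
        traj = TrajectoryEnsemble(pos, pos.copy(), 0.02, (6.4, 6.4), seed=0)
        optics = OpticsModel(
            image_shape=(64, 64),
            background=50.0,
            peak_intensity=150.0,
            bit_depth=8,
            read_noise_sigma=0.0,
            shot_noise=False,
        )
        with pytest.warns(UserWarning, match="clipped"):
            stack = syn.render_movie(traj, optics, seed=0)
        assert stack.meta["render_report"]["clipped_pixels"] > 0

    def test_render_seed_determinism(self):
        traj = syn.simulate_trajectories(
            MotionModel.brownian(0.3), 20, 5, 0.02, (6.4, 6.4), seed=3
        )
        optics = OpticsModel(image_shape=(64, 64))
        a = syn.render_movie(traj, optics, seed=5)
        b = syn.render_movie(traj, optics, seed=5)
        assert np.array_equal(a.frames, b.frames)


class TestScheduleValidation:
    def test_elapsed_times_must_increase(self):
        st = syn.Stage(10.0, MotionModel.brownian(0.1), 2.0)
        with pytest.raises(ParameterError):
            syn.GelationSchedule(stages=[st, st])

    def test_default_schedule_spans_sol_to_gel(self):
        sched = syn.GelationSchedule.acid_milk_default()
        kinds = [s.motion.kind for s in sched.stages]
        assert kinds[0] == "brownian" and "trapped" in kinds
        assert sched.probe_radius == pytest.approx(0.57)


class TestSyntheticRheology:
    def test_noise_free_crossover_is_exact(self):
        trace = loss_tangent(syn.synthesize_rheology(tc=32.0, noise_cv=0.0))
        i = np.where(trace.times == 32.0)[0][0]
        assert np.allclose(trace.tan_delta[i], 1.0)
        assert np.ptp(trace.tan_delta[i]) == 0.0

    def test_noise_free_aging_slope_is_exact(self):
        trace = syn.synthesize_rheology(noise_cv=0.0)
        t_peak = trace.meta["t_peak_min"]
        fit = fit_power_law(trace.times, trace.g_prime[:, 0], window=(t_peak, 90.0))
        assert fit.exponent == pytest.approx(-0.23, abs=1e-12)

    def test_noisy_refit_recovers_exponent(self):
        trace = syn.synthesize_rheology(noise_cv=0.01, seed=5)
        t_peak = trace.meta["t_peak_min"]
        fit = fit_power_law(trace.times, trace.g_prime[:, 0], window=(t_peak, 90.0))
        assert fit.exponent == pytest.approx(-0.23, abs=0.02)

    def test_single_frequency_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            syn.synthesize_rheology(omegas=[1.0])

    @pytest.mark.parametrize(
        "kwargs", [dict(tc=-1.0), dict(aging_exponent_storage=0.1), dict(noise_cv=-0.1)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            syn.synthesize_rheology(**kwargs)
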
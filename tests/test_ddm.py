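"""DDM: structure function, noise/amplitude split, ISF, MSD inversion."""

import numpy as np
import pytest

from gelscope import ddm
from gelscope.ddm import (
    ISFCurve,
    StructureFunction,
    estimate_noise_and_amplitude,
    extract_isf,
    isf_to_msd,
    structure_function,
)
from gelscope.exceptions import AmplitudeError, InsufficientDataError, ShapeError
from gelscope.fitting import fit_stretched_exponential
from gelscope.movie_io import ImageStack


def _stack(frames, dt=0.02, px=0.1):
    return ImageStack(frames, pixel_size=px, frame_interval=dt)


def _brute_force_sf(frames, lag_frames, px):
    """Independent oracle: explicit double-sum DFT plus the declared
    radial binning (annuli one q-spacing wide, DC excluded)."""
    T, L, _ = frames.shape
    modes = np.fft.fftfreq(L, d=1.0 / L)
    power = np.zeros((L, L))
    n = T - lag_frames
    for t in range(n):
        d = frames[t + lag_frames].astype(float) - frames[t].astype(float)
        F = np.zeros((L, L), dtype=complex)
        for k1 in range(L):
            for k2 in range(L):
                phase = np.exp(
                    -2j
                    * np.pi
                    * (np.add.outer(np.arange(L) * k1, np.arange(L) * k2))
                    / L
                )
                F[k1, k2] = (d * phase).sum()
        power += np.abs(F) ** 2
    power /= n * L * L
    kmag = np.sqrt(modes[None, :] ** 2 + modes[:, None] ** 2)
    idx = np.rint(kmag).astype(int)
    out = []
    for b in range(1, L // 2 + 1):
        out.append(power[idx == b].mean())
    return np.array(out)


class TestStructureFunction:
    def test_static_noiseless_movie_is_identically_zero(self):
        frames = np.tile(np.random.default_rng(0).integers(0, 200, (16, 16)), (4, 1, 1))
        sf = structure_function(_stack(frames.astype(np.uint8)), lags=[0.02, 0.04])
        assert np.all(sf.values == 0.0)

    def test_matches_brute_force_dft_on_8x8(self):
        rng = np.random.default_rng(5)
        frames = rng.integers(0, 255, (3, 8, 8)).astype(np.uint8)
        sf = structure_function(_stack(frames), lags=[0.02])
        oracle = _brute_force_sf(frames, 1, 0.1)
        assert np.allclose(sf.values[0], oracle, rtol=1e-10, atol=1e-8)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(2)
        frames = np.rint(1000 + rng.normal(0, 12, (12, 128, 128))).astype(np.uint16)
        sf = structure_function(_stack(frames), lags=[0.02, 0.04, 0.08])
        top = sf.values[0, sf.q_bins.size // 2 :]
        slope = np.polyfit(sf.q_bins[sf.q_bins.size // 2 :], top / top.mean(), 1)[0]
        q_span = sf.q_bins[-1] - sf.q_bins[sf.q_bins.size // 2]
        assert abs(slope) * q_span < 0.05

    def test_q_spacing_matches_field_of_view(self):
        frames = np.zeros((3, 64, 64), dtype=np.uint8)
        frames[1, 2, 3] = 7
        sf = structure_function(_stack(frames, px=0.2), lags=[0.02])
        assert sf.q_bins[0] == pytest.approx(2 * np.pi / (64 * 0.2))
        assert np.allclose(np.diff(sf.q_bins), sf.q_bins[0])

    def test_parseval_under_recorded_normalization(self):
        rng = np.random.default_rng(9)
        frames = rng.integers(0, 4000, (6, 32, 32)).astype(np.uint16)
        sf = structure_function(_stack(frames), lags=[0.02, 0.04])
        assert np.allclose(
            sf.meta["parseval_spectral_sum"],
            sf.meta["parseval_pixel_sum"],
            rtol=1e-8,
        )

    def test_non_square_requires_directive(self):
        frames = np.zeros((3, 32, 48), dtype=np.uint8)
        frames[:, 1, 1] = 3
        with pytest.raises(ShapeError):
            structure_function(_stack(frames), lags=[0.02])
        sf = structure_function(_stack(frames), lags=[0.02], square="crop")
        assert sf.q_bins.size == 16


def _constructed_sf(a0=100.0, b0=10.0, tau0=0.1, n_q=20):
    lags = np.geomspace(1e-4, 10.0, 25)
    q = 0.5 * np.arange(1, n_q + 1)
    values = a0 * (1 - np.exp(-lags[:, None] / tau0)) + b0
    return StructureFunction(
        q_bins=q,
        lags=lags,
        values=np.broadcast_to(values, (25, n_q)).copy(),
        n_pairs=np.full(25, 100),
        pixel_size=0.1,
    )


class TestNoiseAndAmplitude:
    def test_constructed_recovery_within_two_percent(self):
        sf = estimate_noise_and_amplitude(_constructed_sf())
        assert sf.noise_floor_B == pytest.approx(10.0, rel=0.02)
        assert np.allclose(sf.amplitude_A, 100.0, rtol=0.02)
        assert np.all(sf.usable)

    def test_pure_noise_movie_has_no_amplitude(self):
        rng = np.random.default_rng(4)
        frames = np.rint(500 + rng.normal(0, 6, (250, 64, 64))).astype(np.uint16)
        sf = structure_function(
            _stack(frames), lags=[0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.2]
        )
        sf = estimate_noise_and_amplitude(sf)
        assert np.all(np.abs(sf.amplitude_A) < 0.05 * sf.noise_floor_B)

    def test_read_noise_floor_matches_analytic_level(self):
        # Static scene + Gaussian read noise sigma: B = 2 sigma^2 (plus the
        # 1/12 quantization variance) under the per-pixel normalization.
        from gelscope.synthetic import MotionModel, OpticsModel, render_movie, simulate_trajectories

        sigma = 3.0
        traj = simulate_trajectories(
            MotionModel.brownian(0.4), 150, 120, 0.02, (12.8, 12.8), seed=8
        )
        # Dim probes keep the residual high-q scattering amplitude far
        # below the camera noise floor being measured.
        optics = OpticsModel(
            image_shape=(128, 128),
            peak_intensity=40.0,
            read_noise_sigma=sigma,
            shot_noise=False,
        )
        stack = render_movie(traj, optics, seed=9)
        sf = structure_function(stack, lags=[0.02, 0.1, 0.3, 0.6, 1.0, 1.6, 2.3])
        sf = estimate_noise_and_amplitude(sf)
        assert sf.noise_floor_B == pytest.approx(2 * (sigma**2 + 1 / 12), rel=0.10)

    def test_unrelaxed_curve_raises_amplitude_error(self):
        sf = _constructed_sf(tau0=1e4)  # nothing decays inside the window
        sf.values += np.linspace(0, 5, 25)[:, None]  # still drifting
        with pytest.raises(AmplitudeError):
            estimate_noise_and_amplitude(sf)


class TestExtractIsf:
    def test_plateau_maps_to_zero_and_noise_floor_to_one(self):
        sf = estimate_noise_and_amplitude(_constructed_sf())
        isf = extract_isf(sf, q=5.0)
        assert isf.f_values[-1] == pytest.approx(0.0, abs=0.01)  # D at plateau
        assert isf.f_values[0] == pytest.approx(1.0, abs=0.01)  # D = B
        assert isf.q == 5.0

    def test_unusable_bin_rejected(self):
        sf = estimate_noise_and_amplitude(_constructed_sf())
        sf.usable[:] = False
        with pytest.raises(AmplitudeError):
            extract_isf(sf, q=5.0)

    def test_brownian_movie_isf_is_single_exponential(self, brownian_sf):
        isf = extract_isf(brownian_sf, probe_radius=0.57)
        fit = fit_stretched_exponential(isf.lags, isf.f_values, q=isf.q)
        assert fit.beta == pytest.approx(1.0, abs=0.1)
        assert fit.diffusion_coefficient == pytest.approx(0.4, rel=0.10)


class TestIsfToMsd:
    def test_algebraic_identity_for_exponential_isf(self):
        # f = exp(-D q^2 dt) with beta = 1 must invert to exactly 4 D dt.
        q, d = 8.0, 0.3
        lags = np.geomspace(0.02, 1.0, 12)
        isf = ISFCurve(q=q, lags=lags, f_values=np.exp(-d * q**2 * lags))
        msd = isf_to_msd(isf, beta=1.0)
        assert np.allclose(msd.msd, 4 * d * lags, rtol=1e-12)
        assert msd.exponent == pytest.approx(1.0, abs=1e-9)

    def test_stretched_identity_with_matching_beta(self):
        q, beta = 8.0, 0.5
        lags = np.geomspace(0.02, 1.0, 12)
        isf = ISFCurve(q=q, lags=lags, f_values=np.exp(-((lags / 0.2) ** beta)))
        msd = isf_to_msd(isf, beta=beta)
        expected = (4 / q**2) * (lags / 0.2)
        assert np.allclose(msd.msd, expected, rtol=1e-10)

    def test_too_few_invertible_lags_rejected(self):
        isf = ISFCurve(
            q=8.0,
            lags=np.geomspace(0.02, 1.0, 8),
            f_values=np.array([0.5, 0.4, 0.3, 0.2, -0.1, -0.1, -0.1, -0.1]),
        )
        with pytest.raises(InsufficientDataError):
            isf_to_msd(isf)


class TestAcrossQ:
    def test_relaxation_rate_scales_as_q_squared(self, brownian_sf):
        """tau(q) ~ q^-2 across usable bins: the diffusive signature."""
        taus, qs = [], []
        for q_target in [4.0, 5.0, 6.0, 7.0, 9.0, 11.0]:
            isf = extract_isf(brownian_sf, q=q_target)
            fit = fit_stretched_exponential(isf.lags, isf.f_values)
            taus.append(fit.tau)
            qs.append(isf.q)
        slope = np.polyfit(np.log(qs), np.log(taus), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.15)

    def test_msd_magnitude_tracks_viscosity_while_slope_stays_unity(self, viscosity_pair):
        results = {}
        for name, (stack, _, d) in viscosity_pair.items():
            sf = structure_function(
                stack, lags=[f * 0.02 for f in (1, 2, 3, 4, 5, 6, 8, 40, 60, 90, 125)]
            )
            isf = extract_isf(estimate_noise_and_amplitude(sf), q=5.5)
            msd = isf_to_msd(isf)
            results[name] = (msd, d)
        thin, thick = results["thin"], results["thick"]
        assert abs(thin[0].exponent - 1.0) <= 0.08
        assert abs(thick[0].exponent - 1.0) <= 0.08
        # Doubling the viscosity halves the MSD at matching lags.
        common = np.intersect1d(thin[0].lags, thick[0].lags)[:3]
        m_thin = np.interp(common, thin[0].lags, thin[0].msd)
        m_thick = np.interp(common, thick[0].lags, thick[0].msd)
        assert np.all(m_thick < m_thin)
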
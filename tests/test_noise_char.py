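"""Spatial-noise extraction, NUC jump correction, temporal-noise fitting."""

from __future__ import annotations

import numpy as np
import pytest

import thermomimic as tm
from thermomimic import noise_char, synthetic
from thermomimic.core_io import NUCCorrectionParams
from thermomimic.noise_char import (
    correct_nuc_jumps,
    extract_spatial_noise,
    extract_video_temporal_noise,
    fit_temporal_noise_series,
    omega_grid,
)


def _cube(data, fps=10.0):
    return tm.ThermalCube(np.asarray(data, dtype=float), fps=fps)


class TestExtractSpatialNoise:
    def test_constant_cube_gives_zero_beta(self):
        beta = extract_spatial_noise(_cube(np.full((4, 4, 10), 25.0)), 25.0)
        np.testing.assert_allclose(beta.beta, 0.0, atol=1e-12)
        assert beta.n_frames_used == 10

    def test_repeated_fixed_pattern_recovered_exactly(self):
        rng = np.random.default_rng(1)
        pattern = rng.normal(25.0, 0.3, (5, 6))
        data = np.repeat(pattern[:, :, None], 8, axis=2)
        beta = extract_spatial_noise(_cube(data), 25.0)
        np.testing.assert_allclose(beta.beta, pattern - pattern.mean(), atol=1e-12)

    def test_output_always_zero_mean(self):
        rng = np.random.default_rng(2)
        beta = extract_spatial_noise(_cube(20 + rng.normal(0, 0.5, (7, 7, 30))), 20.0)
        assert abs(beta.beta.mean()) < 1e-9


class TestCorrectNucJumps:
    @staticmethod
    def _smooth_series(n=300, fps=10.0):
        t = np.arange(n) / fps
        return 30.0 - 2.0 * np.exp(-0.05 * t)

    def _cube_from_series(self, series):
        return _cube(np.broadcast_to(series, (3, 3, series.size)).copy())

    def test_injected_step_detected_and_removed(self):
        series = self._smooth_series()
        series = series.copy()
        series[100:] += 2.0
        corrected, jumps = correct_nuc_jumps(self._cube_from_series(series))
        assert len(jumps) == 1
        frame, magnitude = jumps[0]
        assert frame == 100
        assert magnitude == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(
            corrected.data.mean(axis=(0, 1)), self._smooth_series(), atol=0.05
        )

    def test_clean_series_unchanged(self):
        cube = self._cube_from_series(self._smooth_series())
        corrected, jumps = correct_nuc_jumps(cube)
        assert jumps == []
        np.testing.assert_array_equal(corrected.data, cube.data)

    def test_opposite_steps_cancel_to_baseline(self):
        series = self._smooth_series().copy()
        series[100:] += 1.0
        series[200:] -= 1.0
        corrected, jumps = correct_nuc_jumps(self._cube_from_series(series))
        assert len(jumps) == 2
        residual = corrected.data.mean(axis=(0, 1)) - self._smooth_series()
        assert residual.max() - residual.min() < 0.1  # equal up to a constant

    def test_idempotent(self):
        series = self._smooth_series().copy()
        series[150:] += 1.5
        once, jumps1 = correct_nuc_jumps(self._cube_from_series(series))
        twice, jumps2 = correct_nuc_jumps(once)
        assert len(jumps1) == 1 and jumps2 == []
        np.testing.assert_array_equal(once.data, twice.data)

    def test_translation_equivariant(self):
        series = self._smooth_series().copy()
        series[80:] += 1.0
        cube = self._cube_from_series(series)
        shifted = _cube(cube.data + 5.0)
        corrected, _ = correct_nuc_jumps(cube)
        corrected_shifted, _ = correct_nuc_jumps(shifted)
        np.testing.assert_allclose(corrected_shifted.data, corrected.data + 5.0, atol=1e-9)


class TestFitTemporalNoise:
    def test_known_cosine_recovered(self):
        fs, period = 1.0, 60.0
        t = np.arange(300) / fs
        series = 2.0 * np.cos(2 * np.pi * t / period)
        a, b, omega, sigma_hf = fit_temporal_noise_series(series, fs, Z=1)
        amplitude = np.hypot(a[1], b[1])
        assert amplitude == pytest.approx(2.0, rel=0.01)
        grid = omega_grid(300, fs)
        step = grid[1] - grid[0]
        assert abs(omega - 2 * np.pi / period) <= step
        # residual reflects only the grid-resolution frequency mismatch
        assert sigma_hf < 0.1

    def test_constant_series_contract(self):
        a, b, omega, sigma_hf = fit_temporal_noise_series(np.full(100, 25.0), 1.0, Z=2)
        assert a[0] == pytest.approx(25.0)
        np.testing.assert_allclose(a[1:], 0.0)
        np.testing.assert_allclose(b, 0.0)
        assert omega == pytest.approx(omega_grid(100, 1.0)[0])
        assert sigma_hf == 0.0

    def test_sigma_hf_monte_carlo(self):
        """σHF estimate within 20% of truth at n=1000 (median of 50 seeds)."""
        fs, n, sigma = 1.0, 1000, 0.05
        t = np.arange(n) / fs
        lf = 0.3 * np.cos(2 * np.pi * t / 120.0)
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            series = lf + rng.normal(0, sigma, n)
            *_, sigma_hf = fit_temporal_noise_series(series, fs, Z=1)
            estimates.append(sigma_hf)
        median = float(np.median(estimates))
        assert abs(median - sigma) / sigma <= 0.20

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(3)
        series = 0.5 * np.cos(2 * np.pi * np.arange(200) / 80.0) + rng.normal(0, 0.1, 200)
        a, b, omega, _ = fit_temporal_noise_series(series, 1.0, Z=2)
        t = np.arange(200)
        design = noise_char._design_matrix(omega, t, 2)
        coef = np.concatenate([[a[0]], [v for z in (1, 2) for v in (a[z], b[z])]])
        resid = series - design @ coef
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_too_short_series_rejected(self):
        with pytest.raises(tm.ValidationError):
            fit_temporal_noise_series(np.zeros(10), 1.0, Z=3)


class TestCharacterizeCamera:
    def test_six_stacks_fill_setpoint_grid(self, quiet_profile):
        stacks = [
            (synthetic.generate_blackbody_stack(quiet_profile, sp, n_frames=40, seed=i),
             float(sp))
            for i, sp in enumerate(synthetic.CHARACTERIZATION_SETPOINTS_C)
        ]
        out = noise_char.characterize_camera(stacks, quiet_profile, Z=1)
        assert sorted(out.spatial_noise) == [15.0, 20.0, 25.0, 30.0, 35.0, 40.0]

    def test_noiseless_stack_gives_zero_noise(self, quiet_profile):
        stack = synthetic.generate_blackbody_stack(
            quiet_profile, 20.0, n_frames=40, seed=0, beta_rms_C=0.0
        )
        out = noise_char.characterize_camera([(stack, 20.0)], quiet_profile, Z=1)
        np.testing.assert_allclose(out.spatial_noise[20.0].beta, 0.0, atol=1e-9)
        np.testing.assert_allclose(out.temporal_noise.sigma_hf, 0.0, atol=1e-9)

    def test_duplicate_setpoints_rejected(self, quiet_profile):
        stack = synthetic.generate_blackbody_stack(quiet_profile, 20.0, n_frames=5, seed=0)
        with pytest.raises(tm.ValidationError):
            noise_char.characterize_camera([(stack, 20.0), (stack, 20.0)], quiet_profile)

    def test_sigma_hf_recovery_from_known_model(self):
        """Median per-detector σHF relative error ≤ 25% over 50 seeds (8×8)."""
        shape, fs, sigma = (8, 8), 2.0, 0.07
        truth = synthetic.make_drift_model(
            shape, fs=fs, amplitude_C=0.3, period_s=60.0, sigma_hf_C=sigma, seed=1
        )
        profile = tm.CameraProfile(name="x", fps=fs, fpa=shape, temporal_noise=truth)
        medians = []
        for seed in range(50):
            stack = synthetic.generate_blackbody_stack(
                profile, 20.0, n_frames=240, seed=seed, beta_rms_C=0.05
            )
            out = noise_char.characterize_camera([(stack, 20.0)], profile, Z=3)
            rel_err = np.abs(out.temporal_noise.sigma_hf - sigma) / sigma
            medians.append(np.median(rel_err))
        assert float(np.median(medians)) <= 0.25


class TestExtractVideoTemporalNoise:
    def test_model_exact_cube_gives_negligible_noise(self, small_shape):
        theta = np.array([31.0, -2.0, -0.05, -1.0, -0.5])
        series = tm.generate_trc(theta, 200, 2.0)
        cube = _cube(np.broadcast_to(series, small_shape + (200,)).copy(), fps=2.0)
        model = extract_video_temporal_noise(cube, Z=1)
        assert np.abs(model.a[:, :, 1:]).max() < 1e-6
        assert np.abs(model.b[:, :, 1:]).max() < 1e-6
        assert model.sigma_hf.max() < 1e-6

    def test_known_sinusoid_recovered(self):
        theta = np.array([31.0, -2.0, -0.05, -1.0, -0.5])
        fs, n = 2.0, 240
        t = np.arange(n) / fs
        lf = 0.4 * np.cos(2 * np.pi * t / 60.0)
        data = np.broadcast_to(tm.generate_trc(theta, n, fs) + lf, (4, 4, n)).copy()
        model = extract_video_temporal_noise(_cube(data, fps=fs), Z=1)
        amplitude = np.hypot(model.a[:, :, 1], model.b[:, :, 1])
        assert np.median(amplitude) == pytest.approx(0.4, rel=0.05)

    def test_nan_pixel_flagged_and_excluded(self):
        theta = np.array([31.0, -2.0, -0.05, -1.0, -0.5])
        data = np.broadcast_to(tm.generate_trc(theta, 100, 2.0), (3, 3, 100)).copy()
        data[1, 1, :] = np.nan
        model = extract_video_temporal_noise(_cube(data, fps=2.0), Z=1)
        assert not model.valid_mask[1, 1]
        assert model.valid_mask.sum() == 8


class TestEndToEndVarianceTransfer:
    def test_resynthesized_variance_matches_generator(self):
        """Characterize → synthesize round trip preserves temporal variance.

        Median (over seeds and detectors) ratio of re-synthesized to
        generating per-pixel variance stays within 30%.
        """
        from thermomimic.degrade import synthesize_temporal_noise

        shape, fs, n = (6, 6), 2.0, 240
        truth = synthetic.make_drift_model(
            shape, fs=fs, amplitude_C=0.25, period_s=60.0, sigma_hf_C=0.06, seed=2
        )
        profile = tm.CameraProfile(name="x", fps=fs, fpa=shape, temporal_noise=truth)
        ratios = []
        for seed in range(50):
            stack = synthetic.generate_blackbody_stack(
                profile, 20.0, n_frames=n, seed=seed, beta_rms_C=0.0
            )
            out = noise_char.characterize_camera([(stack, 20.0)], profile, Z=3)
            resynth = synthesize_temporal_noise(out.temporal_noise, n, fs, seed=seed + 1000)
            generated_var = (stack.data - stack.data.mean(axis=2, keepdims=True)).var(axis=2)
            ratios.append(np.median(resynth.var(axis=2) / generated_var))
        assert 0.7 <= float(np.median(ratios)) <= 1.3
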
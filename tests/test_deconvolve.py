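"""Richardson-Lucy EM properties: monotone likelihood, fixed points, oracles."""

import numpy as np
import pytest
from scipy import ndimage

from weakdecon import (DeconvConfig, EncodedStack, PEAK_ONE, SUM_ONE,
                       estimate_background, flux_correction, richardson_lucy,
                       renormalize_psf, SimConfig, simulate_stack)
from weakdecon.optics import PSFVolume


def _gauss_psf(shape_zyx, sigma=(0.8, 1.2, 1.2)):
    vals = np.zeros(shape_zyx)
    origin = tuple(s // 2 for s in shape_zyx)
    vals[origin] = 1.0
    vals = ndimage.gaussian_filter(vals, sigma, mode="constant")
    oz, oy, ox = origin
    return PSFVolume(vals / vals.sum(), (1.0, 1.0, 1.0), (ox, oy, oz), SUM_ONE)


def _delta_psf(shape_zyx):
    vals = np.zeros(shape_zyx)
    origin = tuple(s // 2 for s in shape_zyx)
    vals[origin] = 1.0
    oz, oy, ox = origin
    return PSFVolume(vals, (1.0, 1.0, 1.0), (ox, oy, oz), SUM_ONE)


def _reference_rl(d, psf_vals, iters, b=0.0):
    """Independent direct-iteration oracle using spatial-domain convolution.

    Requires odd kernel dimensions so the kernel center is unambiguous.
    """
    assert all(s % 2 == 1 for s in psf_vals.shape)
    x = np.full_like(d, max(np.mean(np.maximum(d - b, 0.0)), 1e-12))
    rev = psf_vals[::-1, ::-1, ::-1]
    for _ in range(iters):
        m = ndimage.convolve(x, psf_vals, mode="constant", cval=0.0) + b
        m = np.maximum(m, 1e-30)
        ratio = np.where(d > 0, d / m, 0.0)
        x = x * ndimage.convolve(ratio, rev, mode="constant", cval=0.0)
    return x


class TestFixedPointsAndPositivity:
    def test_delta_psf_identity_after_one_iteration(self):
        rng = np.random.default_rng(0)
        d = rng.poisson(2.0, size=(4, 12, 12)).astype(float)
        psf = _delta_psf((4, 12, 12))
        res = richardson_lucy(d, psf, DeconvConfig(iterations=1, background=0.0))
        np.testing.assert_allclose(res.estimate, d, rtol=1e-9, atol=1e-9)
        res40 = richardson_lucy(d, psf, DeconvConfig(iterations=5, background=0.0))
        np.testing.assert_allclose(res40.estimate, d, rtol=1e-9, atol=1e-9)

    def test_all_zero_observed_returns_zero_estimate(self):
        psf = _gauss_psf((4, 8, 8))
        res = richardson_lucy(np.zeros((4, 8, 8)), psf,
                              DeconvConfig(iterations=10, background=0.0))
        assert res.iterations_run == 0
        assert not res.estimate.any()

    def test_estimates_stay_finite_and_nonnegative(self):
        rng = np.random.default_rng(1)
        d = rng.poisson(0.3, size=(6, 20, 20)).astype(float)
        psf = _gauss_psf((6, 20, 20))
        res = richardson_lucy(d, psf, DeconvConfig(iterations=40, background=0.0))
        assert np.all(np.isfinite(res.estimate))
        assert np.all(res.estimate >= 0)

    def test_requires_sum_one_psf(self):
        psf = _gauss_psf((4, 8, 8))
        peak = renormalize_psf(psf, PEAK_ONE)
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((4, 8, 8)), peak, DeconvConfig())


class TestLikelihoodAndOracles:
    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(2)
        truth = np.zeros((6, 24, 24))
        truth[3, 8, 8] = 30.0
        truth[3, 15, 17] = 20.0
        psf = _gauss_psf((6, 24, 24))
        from weakdecon._fft import LinearConvolver
        conv = LinearConvolver(psf.values, psf.origin_zyx, truth.shape)
        d = rng.poisson(conv.convolve(truth) + 0.05)
        res = richardson_lucy(d.astype(float), psf,
                              DeconvConfig(iterations=30, background=0.05))
        trace = np.array(res.log_likelihood_trace)
        assert len(trace) == 30
        assert np.all(np.diff(trace) >= -1e-9)

    def test_rmse_to_truth_decreases_on_noiseless_phantom(self):
        """Two-impulse phantom, d = H truth exactly: RMSE strictly falls for 10 iters."""
        truth = np.zeros((8, 32, 32))
        truth[4, 10, 10] = 50.0
        truth[4, 20, 24] = 80.0
        psf = _gauss_psf((8, 32, 32))
        from weakdecon._fft import LinearConvolver
        conv = LinearConvolver(psf.values, psf.origin_zyx, truth.shape)
        d = np.clip(conv.convolve(truth), 0, None)
        rmses = []
        for iters in range(1, 11):
            res = richardson_lucy(d, psf, DeconvConfig(iterations=iters, background=0.0))
            rmses.append(float(np.sqrt(np.mean((res.estimate - truth) ** 2))))
        assert all(b < a for a, b in zip(rmses, rmses[1:]))

    def test_matches_direct_iteration_oracle(self):
        """FFT path equals an independent spatial-domain RL on a small phantom."""
        rng = np.random.default_rng(3)
        truth = np.zeros((5, 17, 17))
        truth[2, 6, 6] = 40.0
        psf = _gauss_psf((5, 17, 17), sigma=(0.6, 1.0, 1.0))
        from weakdecon._fft import LinearConvolver
        conv = LinearConvolver(psf.values, psf.origin_zyx, truth.shape)
        d = rng.poisson(conv.convolve(truth) + 0.1).astype(float)
        res = richardson_lucy(d, psf, DeconvConfig(iterations=8, background=0.1))
        expected = _reference_rl(d, psf.values, 8, b=0.1)
        np.testing.assert_allclose(res.estimate, expected, rtol=1e-7, atol=1e-10)

    def test_shift_equivariance_on_interior_content(self):
        psf = _gauss_psf((6, 24, 24))
        d = np.zeros((6, 24, 24))
        d[3, 10:13, 10:13] = [[1, 3, 1], [3, 9, 3], [1, 3, 1]]
        res_a = richardson_lucy(d, psf, DeconvConfig(iterations=10, background=0.0))
        res_b = richardson_lucy(np.roll(d, 1, axis=2), psf,
                                DeconvConfig(iterations=10, background=0.0))
        shifted = np.roll(res_a.estimate, 1, axis=2)
        interior = (slice(None), slice(4, 20), slice(4, 20))
        np.testing.assert_allclose(res_b.estimate[interior], shifted[interior],
                                   rtol=1e-6, atol=1e-9)

    def test_agrees_with_skimage_reference(self):
        """Cross-check against scikit-image's RL (no background) on a phantom."""
        skimage_restoration = pytest.importorskip("skimage.restoration")
        truth = np.zeros((7, 21, 21))
        truth[3, 10, 10] = 100.0
        truth[3, 5, 14] = 60.0
        psf = _gauss_psf((7, 21, 21), sigma=(0.6, 1.0, 1.0))
        from weakdecon._fft import LinearConvolver
        conv = LinearConvolver(psf.values, psf.origin_zyx, truth.shape)
        d = np.clip(conv.convolve(truth), 0, None)
        ours = richardson_lucy(d, psf, DeconvConfig(iterations=15, background=0.0))
        theirs = skimage_restoration.richardson_lucy(d, psf.values, num_iter=15,
                                                     clip=False, filter_epsilon=None)
        # different initialization (flat mean vs 0.5); compare reconstructions loosely
        corr = np.corrcoef(ours.estimate.ravel(), theirs.ravel())[0, 1]
        assert corr > 0.999
        assert ours.estimate.sum() == pytest.approx(theirs.sum(), rel=0.01)


class TestBackground:
    def test_constant_stack_mode(self):
        stack = EncodedStack(np.full((2, 4, 4), 3, dtype=np.uint8), 0.5)
        assert estimate_background(stack) == pytest.approx(1.5)

    def test_simulated_weak_background_estimates_zero(self, default_psf):
        """Poisson(0.01) background yields code 0 at >99% of voxels -> mode 0."""
        cfg = SimConfig(seed=5, background=0.01)
        encoded, _, _, _ = simulate_stack(cfg, default_psf)
        assert estimate_background(encoded) == 0.0

    def test_tie_breaks_toward_smaller_value(self):
        vals = np.array([[[0, 0, 1, 1, 2]]], dtype=np.uint8)
        assert estimate_background(EncodedStack(vals, 1.0)) == 0.0

    def test_manual_override_bypasses_estimation(self):
        d = np.ones((4, 8, 8))
        psf = _delta_psf((4, 8, 8))
        res = richardson_lucy(d, psf, DeconvConfig(iterations=1, background=0.8))
        assert res.background_used == pytest.approx(0.8)

    def test_background_above_max_is_flagged(self):
        d = np.full((2, 4, 4), 0.5)
        psf = _delta_psf((2, 4, 4))
        res = richardson_lucy(d, psf, DeconvConfig(iterations=1, background=2.0))
        assert any("exceeds" in f for f in res.flags)


class TestFluxCorrection:
    def _result(self, estimate):
        from weakdecon.deconvolve import DeconvResult
        return DeconvResult(np.asarray(estimate, float), 1, [], 0.0)

    def test_already_matched_gives_scale_one(self):
        d = np.full((1, 2, 2), 2.0)
        res = flux_correction(self._result(d.copy()), d, 0.0)
        assert res.flux_scale == pytest.approx(1.0)

    def test_doubling_target_doubles_voxels(self):
        est = np.full((1, 2, 2), 1.0)
        d = np.full((1, 2, 2), 2.0)
        res = flux_correction(self._result(est), d, 0.0)
        np.testing.assert_allclose(res.estimate, 2.0)
        assert res.flux_scale == pytest.approx(2.0)

    def test_zero_estimate_flagged_not_scaled(self):
        res = flux_correction(self._result(np.zeros((1, 2, 2))), np.ones((1, 2, 2)), 0.0)
        assert not res.estimate.any()
        assert any("flux" in f for f in res.flags)

    def test_background_subtracted_from_target(self):
        est = np.full((1, 2, 2), 1.0)
        d = np.full((1, 2, 2), 3.0)
        res = flux_correction(self._result(est), d, 1.0)
        assert res.estimate.sum() == pytest.approx(8.0)  # 4 voxels x (3 - 1)
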
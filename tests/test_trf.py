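import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import ols_deconvolve, ols_predict
from trfaad.core import FeatureSignal, TimeSeriesBlock, TRFKernel
from trfaad.errors import InvalidArgumentError, ZeroVarianceError
from trfaad.synth import _convolve_kernel, synthesize_envelope, synthesize_kernel
from trfaad.trf import (
    BoostingConfig,
    boosting_fit,
    make_basis,
    make_lag_grid,
    pearson_r,
    predict_forward,
    reconstruct_backward,
)


def _impulse_kernel(lag_range, fs, at_lag=0.0, direction="forward", n_channels=1,
                    amplitude=1.0, channel=0):
    lags = make_lag_grid(lag_range, fs)
    coefs = np.zeros((lags.size, n_channels))
    coefs[np.argmin(np.abs(lags - at_lag)), channel] = amplitude
    return TRFKernel(coefs=coefs, lags=lags, fs=fs, direction=direction)


class TestBasis:
    def test_full_lag_grid_count(self):
        lags = make_lag_grid((-1.0, 1.0), 50.0)
        assert lags.size == 101
        basis = make_basis(lags.size, fs=50.0)
        assert basis.n_functions == 101

    def test_window_support_three_taps(self):
        basis = make_basis(51, width=50.0, fs=50.0)
        center = 25
        nonzero = np.nonzero(basis.matrix[:, center])[0]
        assert list(nonzero) == [center - 1, center, center + 1]
        assert basis.matrix[center, center] == pytest.approx(1.0)

    def test_zero_weights_zero_kernel(self):
        basis = make_basis(21, fs=50.0)
        assert not np.any(basis.reconstruct(np.zeros(21)))

    def test_subsample_width_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_basis(10, width=5.0, fs=50.0)


class TestPredictForward:
    def test_identity_kernel(self):
        fs = 50.0
        x = FeatureSignal(np.random.default_rng(0).standard_normal(200), fs)
        k = _impulse_kernel((-0.1, 0.1), fs, at_lag=0.0, n_channels=3)
        k.coefs[:, 1] = k.coefs[:, 0]
        k.coefs[:, 2] = k.coefs[:, 0]
        y = predict_forward(k, x)
        for ch in range(3):
            np.testing.assert_allclose(y.data[ch], x.values)

    def test_unit_shift(self):
        fs = 50.0
        k = _impulse_kernel((0, 0.1), fs, at_lag=1 / fs)
        y = predict_forward(k, FeatureSignal([1.0, 0.0, 0.0, 0.0, 0.0, 0.0], fs))
        np.testing.assert_allclose(y.data[0][:3], [0.0, 1.0, 0.0])

    def test_zero_kernel(self):
        fs = 50.0
        lags = make_lag_grid((-0.1, 0.1), fs)
        k = TRFKernel(np.zeros((lags.size, 2)), lags, fs, "forward")
        y = predict_forward(k, FeatureSignal(np.ones(50), fs))
        assert not np.any(y.data)

    def test_rate_mismatch_rejected(self):
        k = _impulse_kernel((0, 0.1), 50.0)
        with pytest.raises(InvalidArgumentError):
            predict_forward(k, FeatureSignal(np.ones(10), 100.0))


class TestReconstructBackward:
    def test_single_channel_identity(self):
        fs = 50.0
        k = _impulse_kernel((-0.1, 0.1), fs, at_lag=0.0, direction="backward")
        y = TimeSeriesBlock(np.random.default_rng(1).standard_normal((1, 100)), fs)
        xhat = reconstruct_backward(k, y)
        np.testing.assert_allclose(xhat.values, y.data[0])

    def test_two_channel_average(self):
        fs = 50.0
        lags = make_lag_grid((-0.1, 0.1), fs)
        coefs = np.zeros((lags.size, 2))
        coefs[np.argmin(np.abs(lags)), :] = 0.5
        k = TRFKernel(coefs, lags, fs, "backward")
        sig = np.random.default_rng(2).standard_normal(80)
        y = TimeSeriesBlock(np.vstack([sig, sig]), fs)
        np.testing.assert_allclose(reconstruct_backward(k, y).values, sig)

    def test_negative_lag_sign_convention(self):
        # Impulse at lag -1 sample: xhat(k) = y(k-1)
        fs = 50.0
        k = _impulse_kernel((-0.1, 0.1), fs, at_lag=-1 / fs, direction="backward")
        y = TimeSeriesBlock(np.array([[1.0, 0.0, 0.0]]), fs)
        np.testing.assert_allclose(reconstruct_backward(k, y).values, [0.0, 1.0, 0.0])

    def test_channel_mismatch_rejected(self):
        fs = 50.0
        k = _impulse_kernel((-0.1, 0.1), fs, direction="backward", n_channels=2)
        with pytest.raises(InvalidArgumentError):
            reconstruct_backward(k, TimeSeriesBlock(np.zeros((3, 10)), fs))


class TestAdjointConsistency:
    def test_forward_backward_agree_on_interior(self):
        fs = 50.0
        rng = np.random.default_rng(3)
        lags = make_lag_grid((-0.2, 0.2), fs)
        h = rng.standard_normal(lags.size)
        fwd = TRFKernel(h[:, None], lags, fs, "forward")
        bwd = TRFKernel(h[::-1][:, None], lags, fs, "backward")
        z = rng.standard_normal(500)
        y_fwd = predict_forward(fwd, FeatureSignal(z, fs)).data[0]
        y_bwd = reconstruct_backward(bwd, TimeSeriesBlock(z[None, :], fs)).values
        pad = lags.size
        np.testing.assert_allclose(y_fwd[pad:-pad], y_bwd[pad:-pad], atol=1e-9)


class TestPearson:
    def test_perfect_correlation(self):
        a = np.random.default_rng(0).standard_normal(100)
        assert pearson_r(a, a) == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = np.random.default_rng(1).standard_normal(100)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_printed_toy_vectors(self):
        assert abs(pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) - 0.6) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            pearson_r([1, 2], [1, 2, 3])

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 100),
        shift=st.floats(-50, 50),
        seed=st.integers(0, 1000),
    )
    def test_scale_shift_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        r0 = pearson_r(a, b)
        r1 = pearson_r(scale * a + shift, b)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(60), rng.standard_normal(60)
        assert pearson_r(a, b) == pytest.approx(pearson_r(b, a), abs=1e-14)


class TestCandidateScanFallback:
    def test_numpy_fallback_matches_compiled_scan(self):
        # the pure-numpy candidate scan must agree with the numba path
        import trfaad.trf as trf_mod

        rng = np.random.default_rng(0)
        r = rng.standard_normal(400)
        C = np.ascontiguousarray(rng.standard_normal((30, 400)))
        step = 0.05
        compiled = trf_mod._best_candidate(r, C, step)

        # re-create the fallback implementation path
        def fallback(r, C, step):
            base = np.abs(r).sum()
            best_err, best_q, best_sign = base, -1, 0.0
            ep = np.abs(r[None, :] - step * C).sum(axis=1)
            em = np.abs(r[None, :] + step * C).sum(axis=1)
            for j in range(C.shape[0]):
                if ep[j] < best_err:
                    best_err, best_q, best_sign = ep[j], j, 1.0
                if em[j] < best_err:
                    best_err, best_q, best_sign = em[j], j, -1.0
            return best_q, best_sign, best_err, base

        ref = fallback(r, C, step)
        assert compiled[0] == ref[0]
        assert compiled[1] == ref[1]
        assert compiled[2] == pytest.approx(ref[2], rel=1e-12)


class TestBoosting:
    def test_forward_kernel_recovery_noiseless(self):
        fs = 50.0
        env = synthesize_envelope(200, fs, seed=1, window_ms=40).data[0]
        env = (env - env.mean()) / env.std()
        truth = synthesize_kernel(
            [(40, 0.5, 15), (100, -0.8, 25), (180, 1.0, 35)], (-0.3, 0.5), fs, [1.0]
        )
        y = _convolve_kernel(env, truth)
        cfg = BoostingConfig(step_size=0.01, partitions=2, patience=20)
        k = boosting_fit(
            TimeSeriesBlock(env[None, :], fs), TimeSeriesBlock(y, fs),
            (-0.3, 0.5), cfg=cfg,
        )
        assert pearson_r(k.coefs[:, 0], truth.coefs[:, 0]) >= 0.9

    def test_null_targets_no_spurious_fit(self):
        fs = 50.0
        rng = np.random.default_rng(7)
        env = synthesize_envelope(120, fs, seed=2).data[0]
        env = (env - env.mean()) / env.std()
        noise = rng.standard_normal(env.size)
        cfg = BoostingConfig(step_size=0.02, partitions=2, patience=10)
        k = boosting_fit(
            TimeSeriesBlock(env[None, :], fs), TimeSeriesBlock(noise[None, :], fs),
            (-0.2, 0.4), cfg=cfg,
        )
        pred = predict_forward(k, FeatureSignal(env, fs)).data[0]
        if pred.std() > 0:
            assert abs(pearson_r(pred, noise)) < 3 / np.sqrt(noise.size)

    def test_standard_lag_grid(self):
        fs = 50.0
        rng = np.random.default_rng(8)
        x = TimeSeriesBlock(rng.standard_normal((1, 600)), fs)
        y = TimeSeriesBlock(rng.standard_normal((1, 600)), fs)
        cfg = BoostingConfig(step_size=0.05, partitions=2, patience=3, max_steps=50)
        k = boosting_fit(x, y, (-1.0, 1.0), cfg=cfg)
        assert k.n_lags == 101
        assert k.lags[0] == pytest.approx(-1.0)
        assert k.lags[-1] == pytest.approx(1.0)

    def test_degenerate_input_zero_kernel_with_warning(self):
        fs = 50.0
        x = TimeSeriesBlock(np.ones((1, 300)), fs)
        y = TimeSeriesBlock(np.random.default_rng(9).standard_normal((1, 300)), fs)
        with pytest.warns(UserWarning, match="constant"):
            k = boosting_fit(x, y, (-0.1, 0.1))
        assert not np.any(k.coefs)

    def test_basis_closure(self):
        fs = 50.0
        env = synthesize_envelope(60, fs, seed=3, window_ms=40).data[0]
        env = (env - env.mean()) / env.std()
        truth = synthesize_kernel([(100, 1.0, 20)], (-0.1, 0.3), fs, [1.0])
        y = _convolve_kernel(env, truth)
        cfg = BoostingConfig(step_size=0.02, partitions=2, patience=10, max_steps=500)
        k = boosting_fit(
            TimeSeriesBlock(env[None, :], fs), TimeSeriesBlock(y, fs),
            (-0.1, 0.3), cfg=cfg,
        )
        np.testing.assert_allclose(
            k.coefs[:, 0], k.basis.reconstruct(k.weights[:, 0]), atol=1e-12
        )

    def test_untouched_weights_exactly_zero(self):
        fs = 50.0
        env = synthesize_envelope(60, fs, seed=4, window_ms=40).data[0]
        env = (env - env.mean()) / env.std()
        truth = synthesize_kernel([(100, 1.0, 20)], (-0.5, 0.5), fs, [1.0])
        y = _convolve_kernel(env, truth)
        cfg = BoostingConfig(step_size=0.02, partitions=2, patience=5, max_steps=200)
        k = boosting_fit(
            TimeSeriesBlock(env[None, :], fs), TimeSeriesBlock(y, fs),
            (-0.5, 0.5), cfg=cfg,
        )
        assert np.sum(k.weights == 0) > 0  # sparsity: untouched weights stay 0

    def test_oracle_equivalence_small_toy(self):
        # 1 channel, 5 lags, noiseless: boosting prediction rho must match
        # OLS deconvolution within 0.02
        fs = 50.0
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        lag_samples = np.arange(0, 5)
        h_true = np.array([0.2, 1.0, -0.6, 0.3, 0.1])
        y = ols_predict(x, h_true, lag_samples)

        h_ols = ols_deconvolve(x, y, lag_samples)
        rho_ols = pearson_r(ols_predict(x, h_ols, lag_samples), y)

        basis = make_basis(5, width=1000.0 / fs, fs=fs)  # effectively no smoothing
        cfg = BoostingConfig(step_size=0.005, partitions=2, patience=50,
                             max_steps=20000)
        k = boosting_fit(
            TimeSeriesBlock(x[None, :], fs), TimeSeriesBlock(y[None, :], fs),
            (0.0, 4 / fs), basis=basis, cfg=cfg,
        )
        pred = predict_forward(k, FeatureSignal(x, fs)).data[0]
        rho_boost = pearson_r(pred, y)
        assert abs(rho_boost - rho_ols) <= 0.02

    def test_backward_fit_recovers_feature(self):
        fs = 50.0
        rng = np.random.default_rng(12)
        feat = synthesize_envelope(120, fs, seed=5, window_ms=40).data[0]
        feat = (feat - feat.mean()) / feat.std()
        # EEG channels: lagged noisy copies of the feature
        eeg = np.vstack([
            np.roll(feat, 3) + 0.3 * rng.standard_normal(feat.size),
            np.roll(feat, 6) + 0.3 * rng.standard_normal(feat.size),
        ])
        cfg = BoostingConfig(step_size=0.02, partitions=2, patience=10, max_steps=2000)
        k = boosting_fit(
            TimeSeriesBlock(eeg, fs), TimeSeriesBlock(feat[None, :], fs),
            (-0.3, 0.3), cfg=cfg, direction="backward",
        )
        xhat = reconstruct_backward(k, TimeSeriesBlock(eeg, fs))
        assert pearson_r(xhat.values, feat) > 0.8
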
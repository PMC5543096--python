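"""The seven denoising techniques: analytic filter responses, SVD
selection rules, regression oracles, kernel properties and the shared
signal-preservation contract."""

import numpy as np
import pytest

import iosproc as ip
from iosproc.simulate import gamma_kernel
from iosproc.techniques import (build_stimulus_sequence, butter_filter,
                                gaussian_kernel, gsr,
                                reconstruct_components, svd_components)

FPT = 150
FS = 15.0


def _pure_response_stack(n_trials=10, shape=(12, 12), amp=0.01, level=1000.0,
                         disturbance=None):
    """Noise-free intensity stack: a blob-shaped absorption dip following
    the gamma-variate response kernel, identical every trial."""
    t = np.arange(FPT) / FS
    kern = gamma_kernel(t, 1.5, 2.0, 1.2)
    r0, c0 = shape[0] // 2, shape[1] // 2
    blob = np.exp(-((np.arange(shape[0])[:, None] - r0) ** 2
                    + (np.arange(shape[1])[None, :] - c0) ** 2) / (2 * 9.0))
    data = level * (1.0 - amp * blob[:, :, None] * np.tile(kern, n_trials)[None, None, :])
    if disturbance is not None:
        data = data * (1.0 + disturbance)[None, None, :]
    return data, kern, (r0, c0)


class TestStimulusSequence:
    def test_printed_values(self):
        w = build_stimulus_sequence(150)
        assert w[10 - 1] == -1    # baseline window
        assert w[50 - 1] == +1    # response window
        assert w[150 - 1] == 0    # tail
        assert w[22 - 1] == -1 and w[23 - 1] == 0
        assert w[40 - 1] == 0 and w[41 - 1] == 1
        assert w[70 - 1] == 1 and w[71 - 1] == 0
        assert set(np.unique(w)) <= {-1.0, 0.0, 1.0}

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_stimulus_sequence(150, windows=[(1, 30, -1), (25, 60, 1)])

    def test_window_outside_trial_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_stimulus_sequence(150, windows=[(100, 200, 1)])


class TestAveraging:
    def test_single_trial_identity(self):
        x = np.random.default_rng(0).normal(size=(4, 4, FPT))
        np.testing.assert_array_equal(
            ip.TrialAverager(FPT).transform(x), x)

    def test_identical_trials_equal_one(self):
        x = np.random.default_rng(1).normal(size=(4, 4, FPT))
        tiled = np.tile(x, (1, 1, 5))
        np.testing.assert_allclose(ip.TrialAverager(FPT).transform(tiled), x,
                                   rtol=1e-12)

    def test_noise_variance_reduced_as_one_over_n(self):
        """signal + white noise, N=25 -> residual variance ~ sigma^2/25."""
        rng = np.random.default_rng(2)
        signal = rng.normal(size=(10, 10, FPT))
        noise = rng.normal(scale=0.5, size=(10, 10, FPT * 25))
        data = np.tile(signal, (1, 1, 25)) + noise
        resid = ip.TrialAverager(FPT).transform(data) - signal
        assert resid.var() == pytest.approx(0.25 / 25, rel=0.2)

    def test_incomplete_trials_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            ip.TrialAverager(FPT).transform(np.ones((2, 2, 200)))


class TestButterworthFilters:
    def test_lowpass_unity_dc_gain(self):
        x = np.full((2, 2, FPT * 4), 3.7)
        out = ip.TemporalLowpass(FPT).transform(x)
        np.testing.assert_allclose(out, 3.7, rtol=1e-9)

    def test_lowpass_kills_heartbeat_frequency(self):
        """|H(6 Hz; fc=0.5, order 10)|^2 = 1/(1+12^20): a 6 Hz sinusoid is
        annihilated (checked away from the filter edge transients)."""
        t = np.arange(FPT * 20) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = butter_filter(x, FS, "low", 10, 0.5)
        core = slice(500, len(t) - 500)
        assert np.sqrt(np.mean(y[core] ** 2)) < 1e-6 * np.sqrt(np.mean(x ** 2))

    def test_lowpass_passband_amplitude_preserved(self):
        t = np.arange(FPT * 40) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = butter_filter(x, FS, "low", 10, 0.5)
        core = slice(1000, len(t) - 1000)
        assert y[core].max() == pytest.approx(1.0, rel=0.01)

    def test_bandpass_removes_dc(self):
        x = np.full(FPT * 10, 5.0)
        y = butter_filter(x, FS, "band", 20, (0.09, 0.5))
        assert np.abs(y[200:-200].mean()) < 1e-6 * 5.0

    def test_bandpass_passes_stimulus_frequency(self):
        t = np.arange(FPT * 60) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y = butter_filter(x, FS, "band", 20, (0.09, 0.5))
        core = slice(3000, len(t) - 3000)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_bandpass_rejects_linear_drift(self):
        t = np.arange(FPT * 60) / FS
        s = np.sin(2 * np.pi * 0.1 * t)
        y = butter_filter(s + 0.02 * t, FS, "band", 20, (0.09, 0.5))
        core = slice(3000, len(t) - 3000)
        assert np.corrcoef(y[core], s[core])[0, 1] > 0.99

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            butter_filter(np.ones(100), FS, "low", 10, 8.0)  # >= Nyquist
        with pytest.raises(ValueError):
            butter_filter(np.ones(100), FS, "band", 20, (0.5, 0.09))

    def test_causal_mode_differs_but_same_band(self):
        t = np.arange(FPT * 20) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        zp = butter_filter(x, FS, "low", 10, 0.5)
        causal = butter_filter(x, FS, "low", 10, 0.5, zero_phase=False)
        assert not np.allclose(zp, causal)  # group delay present
        core = slice(1000, len(t) - 1000)
        assert np.abs(causal[core]).max() == pytest.approx(1.0, rel=0.02)


class TestPCA:
    def test_full_rank_reconstruction_is_identity(self):
        x = np.random.default_rng(3).normal(size=(6, 6, FPT)) + 5.0
        out = ip.PCADenoiser(FPT, keep_fraction=1.0).transform(x)
        np.testing.assert_allclose(out, x, rtol=1e-8, atol=1e-10)

    def test_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=36)
        v = rng.normal(size=FPT)
        x = np.outer(u, v).reshape(6, 6, FPT)
        out = ip.PCADenoiser(FPT, keep_fraction=1 / FPT).transform(x)
        np.testing.assert_allclose(out, x, rtol=1e-7, atol=1e-9)

    def test_denoising_improves_on_noisy_rank_one(self):
        """Eckart-Young: keeping the dominant component of rank-1 signal +
        small noise lands closer (Frobenius) to the clean signal than the
        noisy input is."""
        rng = np.random.default_rng(5)
        clean = np.outer(rng.normal(size=64), rng.normal(size=FPT))
        noisy = clean + rng.normal(scale=0.05, size=clean.shape)
        x = noisy.reshape(8, 8, FPT)
        out = ip.PCADenoiser(FPT, keep_fraction=1 / FPT).transform(x)
        err_out = np.linalg.norm(out.reshape(64, FPT) - clean)
        err_in = np.linalg.norm(noisy - clean)
        assert err_out < err_in

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ip.PCADenoiser(FPT, keep_fraction=0.0).transform(
                np.ones((2, 2, FPT)))


class TestTruncatedDifference:
    def test_pure_tiled_w_selects_single_component(self):
        """Every pixel a scalar multiple of tiled w -> one dominant
        component kept; reconstruction matches the input's fluctuations."""
        rng = np.random.default_rng(6)
        w = build_stimulus_sequence(FPT)
        weights = rng.uniform(0.5, 2.0, size=16)
        x = (weights[:, None] * np.tile(w, 3)[None, :]).reshape(4, 4, FPT * 3)
        est = ip.TruncatedDifference(FPT)
        out = est.transform(x)
        assert len(est.selected_components_) == 1
        a = (out - out.mean(axis=2, keepdims=True)).ravel()
        b = np.tile(w - np.tile(w, 3).mean(), 1)
        b = (weights[:, None] * (w - w.mean())[None, :]).reshape(4, 4, FPT).ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.999

    def test_uncorrelated_high_variance_component_excluded(self):
        """A 1.2 Hz global sinusoid of larger variance than the w-shaped
        response is rejected by the correlation rule while the response
        survives."""
        rng = np.random.default_rng(7)
        w = build_stimulus_sequence(FPT)
        t = np.arange(FPT * 4) / FS
        sine = np.sin(2 * np.pi * 1.2 * t)
        resp_w = rng.uniform(0.2, 1.0, size=25)
        sine_w = rng.uniform(2.0, 4.0, size=25)  # larger variance
        # orthogonal spatial footprints -> the two sources stay separate
        # singular components instead of mixing
        resp_w = resp_w - (resp_w @ sine_w) / (sine_w @ sine_w) * sine_w
        x = (resp_w[:, None] * np.tile(w, 4)[None, :]
             + sine_w[:, None] * sine[None, :]).reshape(5, 5, FPT * 4)
        est = ip.TruncatedDifference(FPT)
        out = est.transform(x)
        # project reconstruction onto the response footprint
        trace = np.einsum("p,pt->t", resp_w,
                          out.reshape(25, FPT)) / (resp_w @ resp_w)
        assert np.corrcoef(trace, w)[0, 1] > 0.99
        # the sinusoid's energy is gone
        amp = np.abs(np.fft.rfft(trace - trace.mean()))
        f = np.fft.rfftfreq(FPT, 1 / FS)
        assert amp[np.argmin(np.abs(f - 1.2))] < 0.05 * amp.max()

    def test_no_selection_raises_helpful_error(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 3, FPT))
        with pytest.raises(ValueError, match="threshold"):
            ip.TruncatedDifference(FPT, threshold_multiplier=1e6).transform(x)

    def test_shares_svd_with_pca_bit_identical(self):
        """With identical component selections the two PCA-family
        techniques produce bit-identical output."""
        rng = np.random.default_rng(9)
        w = build_stimulus_sequence(FPT)
        x = (rng.uniform(0.5, 1.5, size=16)[:, None]
             * np.tile(w, 2)[None, :]).reshape(4, 4, FPT * 2)
        x = x + rng.normal(scale=1e-3, size=x.shape)
        td = ip.TruncatedDifference(FPT)
        out_td = td.transform(x)
        k = len(td.selected_components_)
        if np.array_equal(td.selected_components_, np.arange(k)):
            out_pca = ip.PCADenoiser(FPT, keep_fraction=k / (FPT * 2)).transform(x)
            np.testing.assert_array_equal(out_td, out_pca)


class TestGSR:
    def test_pixel_equal_to_global_is_zeroed(self):
        g = np.random.default_rng(10).normal(size=FPT)
        C = np.tile(g, (5, 1))
        resid, beta = gsr(C)
        np.testing.assert_allclose(beta, 1.0, rtol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_orthogonal_pixel_unchanged(self):
        t = np.arange(FPT)
        g = np.sin(2 * np.pi * 5 * t / FPT)
        c = np.cos(2 * np.pi * 5 * t / FPT)  # orthogonal over full periods
        resid, beta = gsr(np.stack([g, c]), g=g)
        assert abs(beta[1]) < 1e-10
        np.testing.assert_allclose(resid[1], c, atol=1e-10)

    def test_beta_matches_inner_product_oracle(self):
        rng = np.random.default_rng(11)
        C = rng.normal(size=(20, FPT))
        g = rng.normal(size=FPT)
        _, beta = gsr(C, g=g)
        for i in range(20):
            assert beta[i] == pytest.approx(
                float(g @ C[i]) / float(g @ g), rel=1e-10)

    def test_zero_global_signal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gsr(np.zeros((4, FPT)))

    def test_residuals_orthogonal_to_global_signal(self):
        """Exact orthogonalisation: every residual pixel series has
        vanishing inner product with g(t)."""
        rng = np.random.default_rng(12)
        C = rng.normal(size=(30, FPT * 2))
        resid, _ = gsr(C)
        g = C.mean(axis=0)
        inner = np.abs(resid @ g)
        bound = 1e-8 * np.linalg.norm(resid, axis=1) * np.linalg.norm(g)
        assert np.all(inner <= bound + 1e-15)


class TestSpatialGaussian:
    def test_constant_frame_unchanged(self):
        x = np.full((20, 20, FPT), 4.2)
        out = ip.SpatialGaussian(FPT, sigma_um=200.0, pixel_pitch_um=20.0).transform(x)
        np.testing.assert_allclose(out, 4.2, rtol=1e-10)

    def test_impulse_response_is_sampled_kernel(self):
        """An interior unit impulse maps to the discretised, renormalised
        Gaussian kernel."""
        sigma_px = 2.0
        k = gaussian_kernel(sigma_px)
        r = k.shape[0] // 2
        x = np.zeros((41, 41, FPT))
        x[20, 20, :] = 1.0
        out = ip.SpatialGaussian(FPT, sigma_um=2.0 * 20.0,
                                 pixel_pitch_um=20.0).transform(x)
        np.testing.assert_allclose(out[20 - r:20 + r + 1, 20 - r:20 + r + 1, 0],
                                   k, rtol=1e-6, atol=1e-12)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(13)
        x = np.zeros((31, 31, FPT))
        x[12:19, 12:19, :] = rng.uniform(1, 2, size=(7, 7, FPT))
        out = ip.SpatialGaussian(FPT, sigma_um=40.0, pixel_pitch_um=20.0).transform(x)
        assert out[:, :, 0].sum() == pytest.approx(x[:, :, 0].sum(), rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ip.SpatialGaussian(FPT, sigma_um=-1.0).transform(np.ones((4, 4, FPT)))


class TestSharedContracts:
    TECH_PARAMS = {
        "averaging": {},
        "lowpass": {},
        "bandpass": {},
        "pca": {},
        "truncdiff": {},
        "gaussian": {"pixel_pitch_um": 60.0},
    }

    @pytest.mark.parametrize("name", sorted(TECH_PARAMS))
    def test_shape_is_single_trial_equivalent(self, name):
        data, _, _ = _pure_response_stack(n_trials=3)
        est = ip.make_technique(name, frames_per_trial=FPT,
                                **self.TECH_PARAMS[name])
        assert est.transform(data).shape == (12, 12, FPT)

    @pytest.mark.parametrize("name", sorted(TECH_PARAMS))
    def test_response_survives_processing(self, name):
        """On noise-free repeated trials of a pure blob response, every
        technique's ROI trace still correlates > 0.95 with the response
        kernel (transient frames excluded for the filters)."""
        data, kern, (r0, c0) = _pure_response_stack(n_trials=10)
        est = ip.make_technique(name, frames_per_trial=FPT,
                                **self.TECH_PARAMS[name])
        out = est.transform(data)
        trace = out[r0 - 3:r0 + 3, c0 - 3:c0 + 3].mean(axis=(0, 1))
        sl = slice(5, FPT - 5)
        c = np.corrcoef(-trace[sl], kern[sl])[0, 1]
        assert c > 0.95, f"{name}: corr {c:.3f}"

    def test_gsr_preserves_local_response_under_global_disturbance(self):
        """GSR's defining regime: a global disturbance dominates g(t), the
        local blob response survives the regression."""
        t = np.arange(FPT * 10) / FS
        d = 0.02 * np.sin(2 * np.pi * 1.37 * t + 0.5)
        data, kern, (r0, c0) = _pure_response_stack(n_trials=10, disturbance=d)
        out = ip.GlobalSignalRegressor(FPT).transform(data)
        trace = out[r0 - 3:r0 + 3, c0 - 3:c0 + 3].mean(axis=(0, 1))
        sl = slice(5, FPT - 5)
        assert np.corrcoef(-trace[sl], kern[sl])[0, 1] > 0.95
        # and the disturbance is gone from the ROI trace
        amp = np.abs(np.fft.rfft(trace - trace.mean()))
        f = np.fft.rfftfreq(FPT, 1 / FS)
        assert amp[np.argmin(np.abs(f - 1.37))] < 0.1 * amp.max()

    def test_gsr_output_orthogonal_to_global_signal(self):
        rng = np.random.default_rng(14)
        data = rng.normal(size=(6, 6, FPT * 2)) + 100.0
        est = ip.GlobalSignalRegressor(FPT, restore_mean=False)
        C = data.reshape(36, FPT * 2)
        resid, _ = gsr(C)
        g = C.mean(axis=0)
        assert np.all(np.abs(resid @ g)
                      <= 1e-8 * np.linalg.norm(resid, axis=1) * np.linalg.norm(g))


class TestSVDComponents:
    def test_matches_numpy_svd_subspace(self):
        rng = np.random.default_rng(15)
        C = rng.normal(size=(30, 80))
        U, s, P = svd_components(C)
        s_ref = np.linalg.svd(C, compute_uv=False)
        np.testing.assert_allclose(s, s_ref, rtol=1e-8)
        np.testing.assert_allclose(reconstruct_components(U, P, np.arange(30)),
                                   C, rtol=1e-8, atol=1e-10)

    def test_tall_and_wide_orientations_agree(self):
        rng = np.random.default_rng(16)
        C = rng.normal(size=(50, 20))
        U1, s1, P1 = svd_components(C)
        U2, s2, P2 = svd_components(C.T)
        np.testing.assert_allclose(s1[:20], s2[:20], rtol=1e-8)
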
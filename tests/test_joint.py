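"""Tests for the two-pass joint baseline + peak estimator."""

import numpy as np
import pytest

from jointdeconv import (
    DeconvolutionConfig,
    PeakShape,
    Spectrum,
    TRUE_PEAK_TABLE,
    build_baseline_operator,
    convolve_peaks,
    deconvolve,
    extract_support,
    recover_baseline,
    reduced_objective_terms,
    solve_B,
    stage1_select,
    stage2_debias,
)
from conftest import dense_A, dense_DtD


def dense_L(shape, n):
    L = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        L[:, j] = convolve_peaks(e, shape)
    return L


class TestReducedObjective:
    def test_matches_dense_assembly_unconstrained(self, rng, small_shape):
        n, mu, lam1, lam2 = 30, 12.0, 0.7, 0.2
        y = rng.normal(2.0, 0.5, size=n)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(
            mu=mu, lambda1=lam1, lambda2=lam2, boundary=None
        )
        prob, _ = reduced_objective_terms(spec, small_shape, cfg)
        L = dense_L(small_shape, n)
        A = dense_A(mu, n)
        Q_ref = L.T @ A @ L + lam2 * np.eye(n)
        q_ref = lam1 - L.T @ A @ y
        for _ in range(4):
            v = rng.normal(size=n)
            np.testing.assert_allclose(prob.apply_Q(v), Q_ref @ v,
                                       atol=1e-10)
        np.testing.assert_allclose(prob.q, q_ref, atol=1e-10)

    def test_boundary_disabled_equals_explicit_ytilde_identity(
        self, rng, small_shape
    ):
        # with the correction off, the y~-dependent term vanishes and the
        # linear term is the plain reduced criterion
        n = 25
        y = rng.normal(1.0, 0.2, size=n)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(mu=5.0, lambda1=0.4, boundary=None)
        prob, op = reduced_objective_terms(spec, small_shape, cfg)
        assert op.y_tilde is None
        L = dense_L(small_shape, n)
        np.testing.assert_allclose(
            prob.q, 0.4 - L.T @ (dense_A(5.0, n) @ y), atol=1e-10
        )

    def test_tiny_mu_limit_vanishes(self, rng, small_shape):
        n = 20
        spec = Spectrum.from_intensity(rng.normal(size=n) + 5.0)
        cfg = DeconvolutionConfig(
            mu=1e-12, lambda1=0.0, lambda2=0.0, boundary=None
        )
        prob, _ = reduced_objective_terms(spec, small_shape, cfg)
        v = rng.normal(size=n)
        assert np.linalg.norm(prob.apply_Q(v)) < 1e-9
        assert np.linalg.norm(prob.q) < 1e-9

    def test_objective_identity_with_constant(self, rng, small_shape):
        # eliminating the baseline shifts the objective by the constant
        # -1/2 y^t A_mu y, identically in x_p
        n, mu, lam1, lam2 = 40, 33.0, 0.9, 0.15
        y = rng.normal(3.0, 1.0, size=n)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(
            mu=mu, lambda1=lam1, lambda2=lam2, boundary=None
        )
        prob, op = reduced_objective_terms(spec, small_shape, cfg)
        L = dense_L(small_shape, n)
        DtD = dense_DtD(n)
        A = dense_A(mu, n)
        C = -0.5 * y @ A @ y
        diffs = []
        for _ in range(10):
            xp = np.maximum(rng.normal(size=n), 0.0)
            xb = solve_B(op, y - L @ xp)
            J = (
                0.5 * np.sum((y - xb - L @ xp) ** 2)
                + 0.5 * mu * xb @ DtD @ xb
                + lam1 * np.sum(xp)
                + 0.5 * lam2 * np.sum(xp**2)
            )
            diffs.append(prob.objective(xp) - J)
        diffs = np.asarray(diffs)
        np.testing.assert_allclose(diffs, C, rtol=1e-8)

    def test_closed_form_baseline_zeroes_gradient(self, rng, small_shape):
        n, mu = 35, 20.0
        y = rng.normal(2.0, 0.4, size=n)
        xp = np.maximum(rng.normal(size=n), 0.0)
        op = build_baseline_operator(mu, n)
        L = dense_L(small_shape, n)
        xb = solve_B(op, y - L @ xp)
        grad = (np.eye(n) + mu * dense_DtD(n)) @ xb - (y - L @ xp)
        assert np.max(np.abs(grad)) < 1e-10


class TestStage1:
    def test_pure_baseline_yields_no_peaks(self, small_shape):
        n = 120
        i = np.arange(n, dtype=float)
        y = 3.0 + 0.5 * np.exp(-i / n)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(mu=500.0, lambda1=1.0)
        xp, rep = stage1_select(spec, small_shape, cfg)
        assert np.max(xp) < 1e-6 * np.max(y)

    def test_noise_free_support_within_two_channels(self, noise_free):
        spec, truth = noise_free
        cfg = DeconvolutionConfig(mu=500.0, lambda1=0.5, tol=1e-4)
        xp, _ = stage1_select(spec, truth.shape, cfg)
        support = extract_support(xp, 1e-8 * np.max(spec.intensity))
        for center, _ in TRUE_PEAK_TABLE:
            assert np.min(np.abs(support - (center - 1))) <= 2

    def test_l1_norm_monotone_in_lambda1(self, noise_free):
        spec, truth = noise_free
        norms = []
        for lam1 in (0.2, 1.0, 3.0):
            cfg = DeconvolutionConfig(mu=500.0, lambda1=lam1, tol=1e-4)
            xp, _ = stage1_select(spec, truth.shape, cfg)
            norms.append(np.sum(xp))
        assert norms[0] >= norms[1] >= norms[2]


class TestExtractSupport:
    def test_single_maximum(self):
        assert list(extract_support(np.array([0.0, 1.0, 0.0]))) == [1]

    def test_plateau_keeps_both_edges(self):
        # mixed strict/non-strict disjunction admits both plateau samples
        assert list(extract_support(np.array([0.0, 1.0, 1.0, 0.0]))) == [1, 2]

    def test_all_zero_empty(self):
        assert extract_support(np.zeros(6)).size == 0

    def test_floor_prunes_small_maxima(self):
        x = np.array([0.0, 0.01, 0.0, 2.0, 0.0])
        assert list(extract_support(x, min_peak_height=0.1)) == [3]

    def test_boundary_samples_one_sided(self):
        assert list(extract_support(np.array([2.0, 1.0, 0.0]))) == [0]
        assert list(extract_support(np.array([0.0, 1.0, 2.0]))) == [2]


class TestStage2AndBaseline:
    def test_full_support_equals_unrestricted_nonneg_solve(
        self, rng, small_shape
    ):
        n = 40
        y = rng.normal(1.5, 0.3, size=n)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(
            mu=30.0, lambda1=0.0, lambda2=0.0, boundary=None, tol=1e-10
        )
        full, _ = stage2_debias(spec, small_shape, np.arange(n), cfg)
        unrestricted, _ = stage1_select(spec, small_shape, cfg)
        np.testing.assert_allclose(full, unrestricted, atol=1e-6)

    def test_noise_free_heights_with_oracle_support(self, noise_free):
        # a supple baseline (small mu) leaks least peak mass, so the
        # support-restricted debias recovers the tabulated heights tightly
        spec, truth = noise_free
        support = np.array([c - 1 for c, _ in TRUE_PEAK_TABLE])
        cfg = DeconvolutionConfig(mu=10.0, lambda1=0.5, tol=1e-8)
        peaks, _ = stage2_debias(spec, truth.shape, support, cfg)
        heights = peaks[support]
        alphas = np.array([h for _, h in TRUE_PEAK_TABLE])
        np.testing.assert_allclose(heights, alphas, rtol=0.02)

    def test_debias_raises_heights(self, noise_free):
        spec, truth = noise_free
        cfg = DeconvolutionConfig(mu=500.0, lambda1=1.5, tol=1e-4)
        stage1, _ = stage1_select(spec, truth.shape, cfg)
        support = extract_support(stage1, 1e-8 * np.max(spec.intensity))
        peaks, _ = stage2_debias(spec, truth.shape, support, cfg)
        assert np.sum(peaks) >= np.sum(stage1)

    def test_empty_support_warns_and_returns_zero(self, small_shape):
        spec = Spectrum.from_intensity(np.full(20, 2.0))
        cfg = DeconvolutionConfig(mu=10.0)
        with pytest.warns(UserWarning, match="empty"):
            peaks, rep = stage2_debias(
                spec, small_shape, np.array([], dtype=int), cfg
            )
        assert np.all(peaks == 0) and rep.converged

    def test_baseline_mu_zero_reproduces_data(self, rng, small_shape):
        y = rng.normal(size=15) + 4.0
        spec = Spectrum.from_intensity(y)
        # mu must be > 0 in the config; use the operator level for mu = 0
        op = build_baseline_operator(0.0, 15)
        np.testing.assert_array_equal(solve_B(op, y), y)

    def test_baseline_large_mu_is_spectrum_mean(self, rng, small_shape):
        y = rng.normal(2.0, 0.7, size=80)
        spec = Spectrum.from_intensity(y)
        cfg = DeconvolutionConfig(mu=1e9, lambda1=0.0, boundary=None)
        xb = recover_baseline(spec, np.zeros(80), small_shape, cfg)
        np.testing.assert_allclose(xb, y.mean(), atol=1e-5)

    @pytest.mark.parametrize("mu", [10.0, 1000.0, 1e6])
    def test_boundary_values_hit_exactly(self, rng, small_shape, mu):
        y = rng.normal(5.0, 1.0, size=60)
        spec = Spectrum.from_intensity(y)
        ybar1, ybarn = 4.5, 5.5
        cfg = DeconvolutionConfig(
            mu=mu, lambda1=0.5, boundary=(ybar1, ybarn)
        )
        res = deconvolve(spec, small_shape, cfg)
        assert abs(res.baseline[0] - ybar1) <= 1e-9 * (1 + abs(ybar1))
        assert abs(res.baseline[-1] - ybarn) <= 1e-9 * (1 + abs(ybarn))


class TestDeconvolve:
    def test_zero_spectrum(self, small_shape):
        spec = Spectrum.from_intensity(np.zeros(30))
        res = deconvolve(spec, small_shape, DeconvolutionConfig(mu=100.0))
        assert np.all(res.peaks == 0)
        np.testing.assert_allclose(res.baseline, 0.0, atol=1e-12)

    def test_deterministic(self, noise_free):
        spec, truth = noise_free
        cfg = DeconvolutionConfig(mu=500.0, lambda1=0.5, tol=1e-4)
        r1 = deconvolve(spec, truth.shape, cfg)
        r2 = deconvolve(spec, truth.shape, cfg)
        np.testing.assert_array_equal(r1.peaks, r2.peaks)
        np.testing.assert_array_equal(r1.baseline, r2.baseline)

    def test_result_invariants(self, noise_free):
        spec, truth = noise_free
        cfg = DeconvolutionConfig(mu=500.0, lambda1=0.5, tol=1e-4)
        res = deconvolve(spec, truth.shape, cfg)
        assert np.all(res.peaks >= 0)
        off = np.setdiff1d(np.arange(spec.n), res.support)
        assert np.all(res.peaks[off] == 0)
        expected_residual = (
            spec.intensity - res.baseline
            - convolve_peaks(res.peaks, truth.shape)
        )
        np.testing.assert_allclose(res.residual, expected_residual,
                                   atol=1e-12)
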
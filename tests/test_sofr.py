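"""Design construction, penalized fitting, prediction and inference."""

import numpy as np
import pandas as pd
import pytest

import movereserve as mr
from movereserve.curves import BinGrid
from movereserve.sofr import (BSplineBasis, QuadratureSpec, beta_pointwise_band,
                              build_design, coefficient_tests, fit_sofr, predict)

GRID = BinGrid()
QUAD = QuadratureSpec.from_bingrid(GRID)


def random_covariates(n, rng):
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n),
        "BMI": rng.normal(27, 4, n)})


def random_smooth_curves(n, rng, scale=100.0, n_harm=20):
    """Full-rank smooth random curves (independent harmonic coefficients).

    Amplitudes decay slowly (j^-1/4) so the curves span well beyond the
    spline dimension and the functional design block is well conditioned.
    """
    s = QUAD.grid
    j = np.arange(1, n_harm + 1)
    phase = 2 * np.pi * np.outer(s, j) / 24.0
    C = rng.normal(0, 1, (n, n_harm)) / j ** 0.25
    D = rng.normal(0, 1, (n, n_harm)) / j ** 0.25
    level = rng.normal(3.0, 0.7, (n, 1))  # varies each curve's integral
    return scale * (level + C @ np.cos(phase).T + D @ np.sin(phase).T)


def synth_fit(n=200, noise=0.0, seed=0, lambda_rule="gcv", beta=None,
              alpha=(1.0, 0.03, 0.2, 0.01), basis=None, scale=100.0):
    rng = np.random.default_rng(seed)
    basis = basis or BSplineBasis()
    cov = random_covariates(n, rng)
    R = random_smooth_curves(n, rng, scale=scale)
    if beta is None:
        beta = lambda s: -5e-4 * np.exp(-0.5 * ((np.asarray(s, float) - 19) / 2) ** 2)
    a0, a1, a2, a3 = alpha
    y = (a0 + a1 * cov.age + a2 * cov.sex + a3 * cov.BMI
         + R @ (beta(QUAD.grid) * QUAD.weights)
         + (rng.normal(0, noise, n) if noise else 0.0))
    Z, F, P = build_design(R, cov, basis, QUAD)
    fit = fit_sofr(np.asarray(y), Z, F, P, lambda_rule=lambda_rule,
                   basis=basis, quad=QUAD)
    return fit, dict(cov=cov, R=R, y=np.asarray(y), beta=beta, Z=Z, F=F, P=P,
                     rng=rng)


class TestBuildDesign:
    def test_zero_curves_give_zero_functional_block(self, rng):
        cov = random_covariates(10, rng)
        Z, F, P = build_design(np.zeros((10, 144)), cov, BSplineBasis(), QUAD)
        assert np.all(F == 0)
        assert Z.shape == (10, 4) and P.shape == (15, 15)

    def test_unit_curves_row_sums_equal_domain_length(self, rng):
        # partition of unity: sum_k F[i,k] = sum_s w_s = 24
        cov = random_covariates(6, rng)
        _, F, _ = build_design(np.ones((6, 144)), cov, BSplineBasis(), QUAD)
        assert np.allclose(F.sum(axis=1), 24.0, atol=1e-10)

    def test_single_constant_basis_reduces_to_integral_feature(self, rng):
        cov = random_covariates(5, rng)
        curves = random_smooth_curves(5, rng)
        basis1 = BSplineBasis(K=1, degree=0)
        _, F, _ = build_design(curves, cov, basis1, QUAD)
        assert F.shape == (5, 1)
        assert np.allclose(F[:, 0], curves @ QUAD.weights, atol=1e-10)

    def test_rank_deficient_scalar_block_warns(self, rng):
        cov = random_covariates(10, rng)
        cov["sex"] = 1.0
        cov["BMI"] = 1.0  # duplicates the intercept twice over
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            build_design(np.ones((10, 144)), cov, BSplineBasis(), QUAD)


class TestFitSofr:
    def test_noiseless_recovery_small_lambda_large_basis(self):
        fit, d = synth_fit(n=150, noise=0.0, seed=1, lambda_rule=1e-10,
                           basis=BSplineBasis(K=25))
        s = np.linspace(0, 24, 481)
        bt = d["beta"](s)
        ise = np.trapezoid((fit.beta(s) - bt) ** 2, s) / np.trapezoid(bt ** 2, s)
        assert ise < 1e-3

    def test_penalty_limit_shrinks_beta_toward_affine(self):
        fit, _ = synth_fit(n=120, noise=1.0, seed=2, lambda_rule=1e13,
                           alpha=(1, 0, 0, 0),
                           beta=lambda s: np.zeros_like(np.asarray(s, float)))
        # second differences of coefficients vanish -> beta affine in s
        assert np.max(np.abs(np.diff(fit.beta_coefs, 2))) < 1e-6

    def test_pure_noise_curve_norm_decreases_with_lambda(self, rng):
        cov = random_covariates(150, rng)
        R = random_smooth_curves(150, rng)
        y = rng.normal(0, 1, 150)
        basis = BSplineBasis()
        Z, F, P = build_design(R, cov, basis, QUAD)
        s = np.linspace(0, 24, 200)
        norms = []
        for lam in (1e-2, 1e4, 1e10):
            f = fit_sofr(y, Z, F, P, lambda_rule=lam, basis=basis, quad=QUAD)
            norms.append(np.trapezoid(f.beta(s) ** 2, s))
        assert norms[0] > norms[1] > norms[2]

    def test_edf_within_bounds_and_sigma2_positive(self):
        fit, _ = synth_fit(n=200, noise=0.5, seed=3)
        K, p = 15, 4
        null_dim = 2  # second-difference penalty
        assert null_dim + p - 1e-9 <= fit.edf <= K + p + 1e-9
        assert fit.sigma2 > 0
        assert fit.lam >= 0

    def test_gcv_local_optimality_on_grid(self):
        fit, _ = synth_fit(n=200, noise=0.8, seed=4)
        tr = fit.criterion_trace
        j = int(np.argmin(tr[:, 1]))
        # grid spacing is 0.25 decades: 4 steps = one decade either way
        if j >= 4:
            assert tr[j, 1] <= tr[j - 4, 1]
        if j + 4 < len(tr):
            assert tr[j, 1] <= tr[j + 4, 1]

    def test_shift_y_moves_only_intercept(self):
        fit0, d = synth_fit(n=150, noise=0.5, seed=5, lambda_rule=10.0)
        fit1 = fit_sofr(d["y"] + 3.0, d["Z"], d["F"], d["P"], lambda_rule=10.0,
                        basis=fit0.basis, quad=QUAD)
        assert fit1.alpha[0] == pytest.approx(fit0.alpha[0] + 3.0, abs=1e-8)
        assert np.allclose(fit1.alpha[1:], fit0.alpha[1:], atol=1e-8)
        assert np.allclose(fit1.beta_coefs, fit0.beta_coefs, atol=1e-8)

    def test_centering_age_moves_only_intercept(self):
        fit0, d = synth_fit(n=150, noise=0.5, seed=6, lambda_rule=10.0)
        Z2 = d["Z"].copy()
        mean_age = Z2[:, 1].mean()
        Z2[:, 1] -= mean_age
        fit1 = fit_sofr(d["y"], Z2, d["F"], d["P"], lambda_rule=10.0,
                        basis=fit0.basis, quad=QUAD)
        assert fit1.alpha[0] == pytest.approx(
            fit0.alpha[0] + fit0.alpha[1] * mean_age, rel=1e-8)
        assert np.allclose(fit1.alpha[1:], fit0.alpha[1:], atol=1e-9)

    def test_nonfinite_response_rejected(self, rng):
        cov = random_covariates(20, rng)
        R = random_smooth_curves(20, rng)
        Z, F, P = build_design(R, cov, BSplineBasis(), QUAD)
        y = np.zeros(20)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_sofr(y, Z, F, P)

    def test_reml_rule_runs_and_is_sane(self):
        fit, _ = synth_fit(n=150, noise=0.8, seed=7, lambda_rule="reml")
        assert fit.lam > 0 and fit.sigma2 > 0
        assert fit.lambda_rule == "reml"


class TestPredict:
    def test_interpolation_limit_near_zero_residuals(self):
        fit, d = synth_fit(n=12, noise=0.3, seed=8, lambda_rule=1e-12,
                           basis=BSplineBasis(K=14))
        yhat = predict(fit, d["R"], d["cov"])
        assert np.allclose(yhat, d["y"], atol=1e-6)

    def test_zero_curve_zero_covariates_returns_intercept(self):
        fit, _ = synth_fit(n=100, noise=0.2, seed=9)
        cov0 = pd.DataFrame({"subject_id": ["x"], "age": [0.0], "sex": [0],
                             "BMI": [0.0]})
        yhat = predict(fit, np.zeros((1, 144)), cov0)
        assert yhat[0] == pytest.approx(fit.alpha[0], abs=1e-12)

    def test_permutation_invariance(self):
        fit, d = synth_fit(n=60, noise=0.5, seed=10)
        perm = np.random.default_rng(0).permutation(60)
        yhat = predict(fit, d["R"], d["cov"])
        yhat_p = predict(fit, d["R"][perm], d["cov"].iloc[perm])
        assert np.allclose(yhat_p, yhat[perm], atol=1e-12)

    def test_grid_mismatch_raises(self):
        fit, _ = synth_fit(n=60, noise=0.5, seed=11)
        with pytest.raises(mr.GridMismatchError):
            predict(fit, np.zeros((2, 100)),
                    random_covariates(2, np.random.default_rng(0)))


class TestBetaBand:
    def test_band_symmetric_about_estimate(self):
        fit, _ = synth_fit(n=150, noise=0.6, seed=12)
        s = np.linspace(0, 24, 97)
        est, lo, hi = beta_pointwise_band(fit, s)
        assert np.allclose(est - lo, hi - est, atol=1e-12)
        assert np.all(lo <= est) and np.all(est <= hi)

    def test_band_width_vanishes_with_noise(self):
        widths = []
        for noise in (0.5, 0.05, 0.005):
            fit, _ = synth_fit(n=300, noise=noise, seed=13)
            s = np.linspace(0, 24, 97)
            est, lo, hi = beta_pointwise_band(fit, s)
            widths.append(np.max(hi - lo))
        assert widths[0] > widths[1] > widths[2]

    def test_across_function_coverage_near_nominal(self):
        # smoothing-covariance bands: coverage averaged across the function
        # and replications should sit near the nominal 95% level
        s = np.linspace(0, 24, 145)
        coverages = []
        for seed in range(20):
            fit, d = synth_fit(n=400, noise=0.5, seed=100 + seed)
            _, lo, hi = beta_pointwise_band(fit, s, level=0.95)
            bt = d["beta"](s)
            coverages.append(np.mean((bt >= lo) & (bt <= hi)))
        assert np.mean(coverages) >= 0.85


class TestCoefficientTests:
    def test_strong_age_effect_highly_significant(self):
        fit, _ = synth_fit(n=500, noise=0.3, seed=15, alpha=(1, 0.05, 0.2, 0.01))
        t = coefficient_tests(fit)
        assert t["scalar"]["age"]["p"] < 1e-3

    def test_z_statistics_invariant_to_response_scaling(self):
        fit0, d = synth_fit(n=200, noise=0.5, seed=16)
        fit1 = fit_sofr(10.0 * d["y"], d["Z"], d["F"], d["P"],
                        basis=fit0.basis, quad=QUAD)
        t0, t1 = coefficient_tests(fit0), coefficient_tests(fit1)
        for name in ("age", "sex", "BMI"):
            assert t1["scalar"][name]["z"] == pytest.approx(
                t0["scalar"][name]["z"], rel=1e-6)
        assert t1["curve"]["stat"] == pytest.approx(t0["curve"]["stat"], rel=1e-6)

    def test_whole_curve_test_detects_real_signal(self):
        fit, _ = synth_fit(n=400, noise=0.3, seed=17)
        assert coefficient_tests(fit)["curve"]["p"] < 1e-3


class TestQuadratureSpec:
    def test_weights_sum_checked(self):
        with pytest.raises(ValueError, match="sum to 24"):
            QuadratureSpec(np.linspace(0, 24, 10), np.ones(10))

    def test_from_bingrid_sums_to_domain(self):
        q = QuadratureSpec.from_bingrid(BinGrid(bin_width_minutes=20))
        assert q.weights.sum() == pytest.approx(24.0, abs=1e-12)
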
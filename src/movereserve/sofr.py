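"""Penalized scalar-on-function regression (SOFR), from first principles.

Model:  y_i = a0 + a1 age_i + a2 sex_i + a3 BMI_i + integral_0^24 beta(s) R_i(s) ds + eps_i

The coefficient function beta(s) is expanded in a cubic B-spline basis
(K = 15 by default, evenly spaced interior knots on [0, 24]) and the
integral discretized by the midpoint rule on the bin midpoints, giving a
functional design block F[i, k] = sum_s w_s R_i(s) B_k(s).  Estimation
minimizes

    || y - Z alpha - F b ||^2  +  lambda * b' P b

with the scalar block Z unpenalized and P a second-order difference
roughness penalty; lambda is selected by GCV (default) or REML.  The
coefficient covariance is the sandwich of the penalized normal equations,
sigma^2 (X'X + lambda P)^-1 X'X (X'X + lambda P)^-1, with
sigma^2 = RSS / (n - edf).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import DimensionError, GridMismatchError

logger = logging.getLogger(__name__)

SCALAR_NAMES = ("intercept", "age", "sex", "BMI")


@dataclass
class QuadratureSpec:
    """Grid (hours) and positive weights summing to the domain length 24."""

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.grid.shape != self.weights.shape:
            raise DimensionError("grid and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if abs(self.weights.sum() - 24.0) > 1e-9:
            raise ValueError(
                f"quadrature weights must sum to 24, got {self.weights.sum():.12g}")

    @classmethod
    def from_bingrid(cls, bingrid) -> "QuadratureSpec":
        """Midpoint rule on the diurnal bin midpoints."""
        S = bingrid.n_bins
        return cls(bingrid.midpoints_hours, np.full(S, 24.0 / S))


@dataclass
class BSplineBasis:
    """B-spline basis on [0, 24] with evenly spaced interior knots."""

    K: int = 15
    degree: int = 3
    domain: tuple = (0.0, 24.0)

    def __post_init__(self):
        n_interior = self.K - self.degree - 1
        if n_interior < 0:
            raise ValueError(f"K={self.K} too small for degree {self.degree}")
        a, b = self.domain
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        self.knots = np.r_[[a] * (self.degree + 1), interior, [b] * (self.degree + 1)]

    def design(self, x) -> np.ndarray:
        """Basis evaluation matrix, len(x) x K (clamped to the domain)."""
        x = np.clip(np.asarray(x, dtype=float), self.domain[0],
                    np.nextafter(self.domain[1], -np.inf))
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        """Difference roughness penalty D'D on the basis coefficients."""
        D = np.diff(np.eye(self.K), n=order, axis=0)
        return D.T @ D


@dataclass
class SofrFit:
    """Fitted SOFR model with everything needed for prediction and inference."""

    alpha: np.ndarray                 # scalar-block coefficients
    beta_coefs: np.ndarray            # K basis coefficients of beta-hat
    basis: BSplineBasis
    quad: QuadratureSpec
    lam: float
    covariance: np.ndarray            # joint (p+K) sandwich covariance
    sigma2: float
    edf: float
    covariance_bayes: np.ndarray = None   # sigma2 (X'X + lam P)^-1 (for bands)
    penalty_order: int = 2
    lambda_rule: str = "gcv"
    criterion_trace: np.ndarray = None   # (lambda, criterion) pairs explored
    scalar_names: tuple = SCALAR_NAMES
    n_obs: int = 0

    @property
    def n_scalar(self) -> int:
        return self.alpha.size

    def beta(self, s) -> np.ndarray:
        """beta-hat evaluated on an arbitrary grid in [0, 24]."""
        return self.basis.design(s) @ self.beta_coefs

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha.tolist(),
            "scalar_names": list(self.scalar_names),
            "beta_coefs": self.beta_coefs.tolist(),
            "basis": {"K": self.basis.K, "degree": self.basis.degree,
                      "knots": self.basis.knots.tolist()},
            "quad_grid": self.quad.grid.tolist(),
            "quad_weights": self.quad.weights.tolist(),
            "lambda": self.lam, "sigma2": self.sigma2, "edf": self.edf,
            "lambda_rule": self.lambda_rule, "n_obs": self.n_obs,
            "covariance": self.covariance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(curves: np.ndarray, covariates, basis: BSplineBasis,
                 quad: QuadratureSpec, penalty_order: int = 2):
    """Scalar block Z = [1, age, sex, BMI], functional block F, penalty P.

    F[i, k] = sum_s w_s * curves[i, s] * B_k(grid_s)  (midpoint quadrature of
    the functional term).
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[1] != quad.grid.size:
        raise DimensionError(
            f"curves must be n x {quad.grid.size}, got {curves.shape}")
    if hasattr(covariates, "columns"):
        cov = np.column_stack([np.ones(len(covariates)),
                               covariates["age"].to_numpy(dtype=float),
                               covariates["sex"].to_numpy(dtype=float),
                               covariates["BMI"].to_numpy(dtype=float)])
    else:
        cov = np.asarray(covariates, dtype=float)
    if cov.shape[0] != curves.shape[0]:
        raise DimensionError("covariates and curves disagree on n")
    if np.linalg.matrix_rank(cov) < cov.shape[1]:
        warnings.warn("scalar design Z is rank deficient; fit proceeds",
                      RuntimeWarning)
    B = basis.design(quad.grid)                       # S x K
    F = curves @ (quad.weights[:, None] * B)          # n x K
    P = basis.penalty(penalty_order)
    return cov, F, P


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _solve_penalized(S, Pfull, r, lam):
    M = S + lam * Pfull
    try:
        c = cho_factor(M, lower=True)
        theta = cho_solve(c, r)
        Minv_S = cho_solve(c, S)
    except LinAlgError:
        # degenerate design (e.g. rank-deficient blocks): minimum-norm
        # solution; rcond well above rounding noise so exactly-flat
        # directions are dropped rather than inverted
        Minv = np.linalg.pinv(M, hermitian=True, rcond=1e-9)
        theta = Minv @ r
        Minv_S = Minv @ S
    return theta, Minv_S


def _default_lambda_grid(F, P):
    scale = max(np.trace(F.T @ F), 1e-12) / max(np.trace(P), 1e-12)
    return scale * np.logspace(-9, 7, 65)


def fit_sofr(y, Z, F, P, lambda_rule="gcv", lambda_grid=None,
             basis: BSplineBasis = None, quad: QuadratureSpec = None,
             penalty_order: int = 2) -> SofrFit:
    """Penalized least squares with unpenalized scalar block.

    ``lambda_rule`` is ``'gcv'``, ``'reml'`` or a fixed non-negative number.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    Z = np.asarray(Z, dtype=float)
    F = np.asarray(F, dtype=float)
    n, p = Z.shape
    K = F.shape[1]
    if y.size != n or F.shape[0] != n:
        raise DimensionError("y, Z and F disagree on n")
    null_dim = K - np.linalg.matrix_rank(P)
    if n <= p + null_dim:
        warnings.warn(f"n = {n} is small for p + penalty null space = "
                      f"{p + null_dim}; fit may be unstable", RuntimeWarning)

    X = np.hstack([Z, F])
    S_raw = X.T @ X
    r_raw = X.T @ y
    yty = float(y @ y)
    Pfull_raw = np.zeros((p + K, p + K))
    Pfull_raw[p:, p:] = P
    # column equilibration: rescale to unit diagonal so the intercept and the
    # (much larger) functional columns solve at comparable precision; the
    # objective and all reported quantities are exactly invariant to this
    diag = np.diag(S_raw)
    d = np.where(diag > 1e-12 * max(diag.max(), 1.0), np.sqrt(diag), 1.0)
    S = S_raw / np.outer(d, d)
    r = r_raw / d
    Pfull = Pfull_raw / np.outer(d, d)

    def rss_edf(lam):
        theta_s, Minv_S = _solve_penalized(S, Pfull, r, lam)
        rss = max(yty - 2.0 * theta_s @ r + theta_s @ S @ theta_s, 0.0)
        edf = float(np.trace(Minv_S))
        return theta_s / d, rss, edf

    if isinstance(lambda_rule, (int, float, np.floating)) and not isinstance(lambda_rule, bool):
        lam = float(lambda_rule)
        if lam < 0:
            raise ValueError("fixed lambda must be >= 0")
        trace = None
        rule_name = "fixed"
    else:
        if lambda_grid is None:
            lambda_grid = _default_lambda_grid(F, P)
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        crits = np.empty(lambda_grid.size)
        for j, lam_j in enumerate(lambda_grid):
            theta_j, rss_j, edf_j = rss_edf(lam_j)
            if lambda_rule == "gcv":
                denom = max(n - edf_j, 1e-8)
                crits[j] = n * rss_j / denom ** 2
            elif lambda_rule == "reml":
                crits[j] = _reml_criterion(S, Pfull, P, r, yty, theta_j,
                                           rss_j, lam_j, n, p, null_dim)
            else:
                raise ValueError(f"unknown lambda rule {lambda_rule!r}")
        if not np.any(np.isfinite(crits)):
            raise RuntimeError(
                f"no lambda with finite {lambda_rule} criterion; "
                f"trace: {list(zip(lambda_grid, crits))[:5]}...")
        lam = float(lambda_grid[np.nanargmin(crits)])
        trace = np.column_stack([lambda_grid, crits])
        rule_name = str(lambda_rule)

    theta, rss, edf = rss_edf(lam)
    sigma2 = rss / max(n - edf, 1e-8)
    sigma2 = max(sigma2, 1e-300)
    M = S + lam * Pfull
    try:
        c = cho_factor(M, lower=True)
        Minv = cho_solve(c, np.eye(p + K))
    except LinAlgError:
        Minv = np.linalg.pinv(M, hermitian=True, rcond=1e-9)
    cov = sigma2 * (Minv @ S @ Minv) / np.outer(d, d)
    cov_bayes = sigma2 * Minv / np.outer(d, d)

    return SofrFit(alpha=theta[:p], beta_coefs=theta[p:], basis=basis,
                   quad=quad, lam=lam, covariance=cov, sigma2=float(sigma2),
                   covariance_bayes=cov_bayes,
                   edf=float(edf), penalty_order=penalty_order,
                   lambda_rule=rule_name, criterion_trace=trace,
                   scalar_names=SCALAR_NAMES[:p], n_obs=n)


def _reml_criterion(S, Pfull, P, r, yty, theta, rss, lam, n, p, null_dim):
    """Negative restricted log-likelihood (up to constants), sigma2 profiled."""
    K = P.shape[0]
    pen = float(theta[p:] @ P @ theta[p:])
    dev = rss + lam * pen
    mp = p + null_dim
    if n <= mp:
        return np.inf
    sign, logdet_M = np.linalg.slogdet(S + lam * Pfull)
    if sign <= 0:
        return np.inf
    eig = np.linalg.eigvalsh(P)
    nz = eig[eig > 1e-10 * eig.max()]
    logdet_pen = nz.size * np.log(lam) + np.log(nz).sum() if lam > 0 else -np.inf
    return (n - mp) * np.log(dev) + logdet_M - logdet_pen


# ---------------------------------------------------------------------------
# prediction and inference
# ---------------------------------------------------------------------------

def predict(fit: SofrFit, curves: np.ndarray, covariates) -> np.ndarray:
    """y-hat = Z alpha-hat + F b-hat on new subjects (same basis/quadrature)."""
    curves = np.asarray(curves, dtype=float)
    if fit.quad is None:
        raise GridMismatchError("fit carries no quadrature spec")
    if curves.shape[1] != fit.quad.grid.size:
        raise GridMismatchError(
            f"curves have {curves.shape[1]} bins, fit expects {fit.quad.grid.size}")
    Z, F, _ = build_design(curves, covariates, fit.basis, fit.quad,
                           fit.penalty_order)
    return Z[:, :fit.n_scalar] @ fit.alpha + F @ fit.beta_coefs


def beta_pointwise_band(fit: SofrFit, s_grid, level: float = 0.95,
                        which: str = "bayes"):
    """beta-hat(s) with pointwise normal confidence bands.

    Returns (estimate, lower, upper) arrays over ``s_grid``.  ``which``
    selects the coefficient covariance: the Bayesian/smoothing covariance
    (default; nominal across-the-function coverage in the Nychka sense,
    accounting for smoothing bias) or the frequentist ``'sandwich'``.
    """
    B = fit.basis.design(s_grid)
    est = B @ fit.beta_coefs
    source = fit.covariance_bayes if (which == "bayes"
                                      and fit.covariance_bayes is not None) \
        else fit.covariance
    cov_b = source[fit.n_scalar:, fit.n_scalar:]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov_b, B), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, est - z * se, est + z * se


def coefficient_tests(fit: SofrFit, curve_df: str = "rank") -> dict:
    """Wald tests for the scalar covariates and the whole curve beta != 0.

    The whole-curve statistic is b-hat' Cov(b-hat)^{-1} b-hat.  With the
    sandwich covariance this is chi-square with rank(Cov) = K degrees of
    freedom under the null for a fixed smoothing parameter (``curve_df=
    'rank'``, the calibrated default); ``'edf'`` uses the effective degrees
    of freedom of the functional block instead.
    """
    out = {"scalar": {}, "curve": {}}
    p = fit.n_scalar
    se = np.sqrt(np.maximum(np.diag(fit.covariance)[:p], 0.0))
    for j, name in enumerate(fit.scalar_names):
        if j == 0:
            continue  # intercept not reported
        if se[j] <= 0:
            out["scalar"][name] = {"z": np.nan, "p": np.nan,
                                   "estimate": float(fit.alpha[j])}
            continue
        z = fit.alpha[j] / se[j]
        out["scalar"][name] = {"estimate": float(fit.alpha[j]),
                               "se": float(se[j]), "z": float(z),
                               "p": float(2 * stats.norm.sf(abs(z)))}
    cov_b = fit.covariance[p:, p:]
    b = fit.beta_coefs
    try:
        c = cho_factor(cov_b, lower=True)
        stat = float(b @ cho_solve(c, b))
        rank = b.size
    except LinAlgError:
        cov_pinv = np.linalg.pinv(cov_b, rcond=1e-10)
        rank = int(np.linalg.matrix_rank(cov_b, tol=1e-10))
        if rank == 0:
            out["curve"] = {"available": False}
            return out
        stat = float(b @ cov_pinv @ b)
    if curve_df == "rank":
        df = float(rank)
    elif curve_df == "edf":
        df = max(fit.edf - p, 1.0)
    else:
        raise ValueError("curve_df must be 'rank' or 'edf'")
    out["curve"] = {"available": True, "stat": stat, "df": df,
                    "p": float(stats.chi2.sf(stat, df))}
    return out


def export_beta_csv(fit: SofrFit, path, s_grid=None, level: float = 0.95) -> None:
    """beta-hat with bands as CSV (s, estimate, lower, upper)."""
    import pandas as pd
    if s_grid is None:
        s_grid = np.linspace(0, 24, 241)
    est, lo, hi = beta_pointwise_band(fit, s_grid, level)
    pd.DataFrame({"s_hours": s_grid, "estimate": est,
                  "lower": lo, "upper": hi}).to_csv(
        path, index=False, float_format="%.10g")
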
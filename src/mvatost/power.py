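"""Probability of declaring equivalence for the multivariate TOST.

The rejection event is the intersection over outcomes of
``|theta_hat_j| <= c - t_{gamma,nu} * sigma_hat_j``, so the rejection
probability is a multivariate-normal rectangle probability whose limits are
random through the estimated standard errors.  With the covariance treated as
known the limits are fixed (normal quantiles) and one rectangle evaluation
suffices; with an estimated covariance the rectangle is averaged over the
scaled-Wishart law of Sigma_hat by Monte Carlo.  Because the rectangle
depends on a Wishart draw only through the square roots of its diagonal, the
sampler keeps just those, and draws with any non-positive upper limit
contribute exactly zero -- which realises both the empty-rectangle convention
and the never-declare bound sigma_hat_j > c / t_{gamma,nu} without explicit
indicator bookkeeping.

Dimension m <= 2 uses a vectorised closed form of the (bivariate) normal CDF
built on Owen's T function; m >= 3 falls back to scipy's Genz algorithm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.special import ndtr, owens_t

from .canonical import (
    EquivalenceSpec,
    MCConfig,
    PopulationModel,
    _validate_pd,
)
from ._wishart import wishart_sqrt_diag

__all__ = [
    "RectangleSpec",
    "mvn_rectangle",
    "power_known_cov",
    "power_estimated_cov",
    "size_independent_known",
    "KnownCovKernel",
    "EstimatedCovKernel",
    "make_kernel",
]


@dataclasses.dataclass(frozen=True)
class RectangleSpec:
    """An axis-aligned rectangle probability problem for an MVN vector."""

    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = _validate_pd(self.cov, "cov")
        m = cov.shape[0]
        if not (lower.shape[0] == upper.shape[0] == mean.shape[0] == m):
            raise ValueError("rectangle dimensions are inconsistent")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


def _bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k), vectorised in h, k.

    Owen (1956): Phi2(h,k;rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta
    with beta = 1/2 iff h*k < 0.  The h=0 / k=0 singularities are removable;
    a 1e-13 nudge keeps the identity exact to ~1e-13.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) >= 1.0 - 1e-14:  # (near-)degenerate: comonotone limits
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, None)
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    den = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * den)
    ak = (h - rho * k) / (k * den)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta


def _rect_prob_std_batch(a: np.ndarray, b: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Rectangle probabilities for standardised limits, batched over rows.

    a, b: (B, m) standardised lower/upper limits; corr: (m, m) correlation.
    """
    m = corr.shape[0]
    if m == 1:
        return ndtr(b[:, 0]) - ndtr(a[:, 0])
    if m == 2:
        rho = float(corr[0, 1])
        return (
            _bvn_cdf(b[:, 0], b[:, 1], rho)
            - _bvn_cdf(a[:, 0], b[:, 1], rho)
            - _bvn_cdf(b[:, 0], a[:, 1], rho)
            + _bvn_cdf(a[:, 0], a[:, 1], rho)
        )
    out = np.empty(a.shape[0])
    mvn = stats.multivariate_normal(mean=np.zeros(m), cov=corr)
    for i in range(a.shape[0]):
        out[i] = mvn.cdf(b[i], lower_limit=a[i])
    return np.clip(out, 0.0, 1.0)


def mvn_rectangle(r: RectangleSpec, tol: float = 1e-6) -> float:
    """P(lower <= X <= upper) for X ~ N(mean, cov); empty rectangles give 0."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    if np.any(r.lower >= r.upper):
        return 0.0
    s = np.sqrt(np.diag(r.cov))
    corr = r.cov / np.outer(s, s)
    a = ((r.lower - r.mean) / s)[None, :]
    b = ((r.upper - r.mean) / s)[None, :]
    return float(np.clip(_rect_prob_std_batch(a, b, corr)[0], 0.0, 1.0))


# ---------------------------------------------------------------------------
# power kernels
# ---------------------------------------------------------------------------


class KnownCovKernel:
    """Declaration probability with Sigma known: fixed limits, z quantiles."""

    is_stochastic = False

    def __init__(self, sigma_mat: np.ndarray, spec: EquivalenceSpec):
        self.sigma_mat = _validate_pd(sigma_mat, "sigma_mat")
        self.spec = spec
        self.s = np.sqrt(np.diag(self.sigma_mat))
        self.corr = self.sigma_mat / np.outer(self.s, self.s)
        self.m = self.s.shape[0]

    def power(self, gamma: float, theta) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        z = stats.norm.isf(gamma)
        u = self.spec.c - z * self.s
        if np.any(u <= 0.0):
            return 0.0
        a = ((-u - theta) / self.s)[None, :]
        b = ((u - theta) / self.s)[None, :]
        return float(np.clip(_rect_prob_std_batch(a, b, self.corr)[0], 0.0, 1.0))

    def power_se(self, gamma: float, theta) -> tuple[float, float]:
        return self.power(gamma, theta), 0.0


class EstimatedCovKernel:
    """Monte Carlo declaration probability under the canonical Wishart model.

    One frozen set of Wishart standard-error draws is generated at
    construction and reused for every (gamma, theta) evaluation (common
    random numbers), so the kernel is a smooth deterministic function of the
    level within a fixed instance -- a property the fixed-point iteration of
    the level adjustment relies on.
    """

    is_stochastic = True

    def __init__(
        self,
        sigma_mat: np.ndarray,
        nu: int,
        spec: EquivalenceSpec,
        mc: MCConfig | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.sigma_mat = _validate_pd(sigma_mat, "sigma_mat")
        self.nu = int(nu)
        self.spec = spec
        self.mc = mc if mc is not None else MCConfig()
        self.s = np.sqrt(np.diag(self.sigma_mat))
        self.corr = self.sigma_mat / np.outer(self.s, self.s)
        self.m = self.s.shape[0]
        if self.nu < self.m:
            raise ValueError(f"nu={nu} < m={self.m}: Wishart density is degenerate")
        if rng is None:
            rng = np.random.default_rng(self.mc.seed)
        chol = np.linalg.cholesky(self.sigma_mat)
        # sigma_hat_j draws, shape (n_draws, m); the only part of Sigma_hat
        # the rejection region depends on
        self.sig_hat = wishart_sqrt_diag(rng, self.nu, chol, self.mc.n_wishart_draws)

    def power_se(self, gamma: float, theta) -> tuple[float, float]:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        tq = stats.t.isf(gamma, self.nu)
        u = self.spec.c - tq * self.sig_hat  # (B, m)
        valid = (u > 0.0).all(axis=1)
        n = u.shape[0]
        probs = np.zeros(n)
        if valid.any():
            uu = u[valid]
            a = (-uu - theta) / self.s
            b = (uu - theta) / self.s
            probs[valid] = np.clip(_rect_prob_std_batch(a, b, self.corr), 0.0, 1.0)
        p = float(probs.mean())
        se = float(probs.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
        return p, se

    def power(self, gamma: float, theta) -> float:
        return self.power_se(gamma, theta)[0]


def make_kernel(
    sigma_mat,
    nu: int | None,
    spec: EquivalenceSpec,
    mc: MCConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Known-covariance kernel when ``nu`` is None, else the Wishart MC kernel."""
    if nu is None:
        return KnownCovKernel(sigma_mat, spec)
    return EstimatedCovKernel(sigma_mat, nu, spec, mc=mc, rng=rng)


# ---------------------------------------------------------------------------
# public power functions
# ---------------------------------------------------------------------------


def power_known_cov(gamma: float, pop: PopulationModel, spec: EquivalenceSpec) -> float:
    """Probability of declaring equivalence with Sigma known, at level gamma."""
    if not 0.0 < gamma < 0.5:
        raise ValueError("gamma must lie in (0, 0.5)")
    return KnownCovKernel(pop.sigma_mat, spec).power(gamma, pop.theta)


def power_estimated_cov(
    gamma: float,
    theta,
    sigma_mat,
    nu: int,
    spec: EquivalenceSpec,
    mc: MCConfig | None = None,
) -> tuple[float, float]:
    """Monte Carlo declaration probability and its standard error.

    Averages the rectangle probability (mean ``theta``, covariance
    ``sigma_mat``) over ``mc.n_wishart_draws`` draws of the estimated
    standard errors, with t quantiles on ``nu`` degrees of freedom.
    """
    if not 0.0 < gamma < 0.5:
        raise ValueError("gamma must lie in (0, 0.5)")
    kern = EstimatedCovKernel(sigma_mat, nu, spec, mc=mc)
    return kern.power_se(gamma, theta)


def size_independent_known(gamma: float, sigma: float, m: int, c: float) -> float:
    """Closed-form test size for a diagonal known covariance sigma^2 I_m.

    size = {1 - Phi(z) - Phi(z - 2c/sigma)} * {1 - 2 Phi(z - c/sigma)}^(m-1)
    with z the upper-gamma standard-normal quantile, evaluated at the least
    favourable boundary point (c, 0, ..., 0); zero whenever the marginal
    interval is empty (c <= z * sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    z = stats.norm.isf(gamma)
    if c - z * sigma <= 0.0:
        return 0.0
    first = 1.0 - ndtr(z) - ndtr(z - 2.0 * c / sigma)
    second = 1.0 - 2.0 * ndtr(z - c / sigma)
    return float(max(first, 0.0) * max(second, 0.0) ** (m - 1))
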
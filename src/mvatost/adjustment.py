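"""Adjusted significance level for the multivariate alpha-TOST.

The conventional multivariate TOST is conservative: its size is strictly
below the nominal level alpha, increasingly so for many outcomes or large
standard errors.  The alpha-TOST runs the very same interval-inclusion test
at a corrected level alpha* >= alpha chosen so that the size equals alpha:

    alpha* = argzero over gamma in [alpha, 0.5) of
             size(gamma; Omega, nu, c) - alpha

where Omega is either the true covariance (population adjustment, alpha*) or
its estimate (feasible adjustment, alpha-hat*).  Because the least favourable
configuration lambda itself moves with the level, the solver alternates an
outer lambda refresh with an inner damped fixed-point iteration

    a_k = a_{k-1} + alpha - p(a_{k-1}, lambda, Omega, nu, c)

which contracts exponentially when the largest standard error is not large
relative to the margin c.  Non-existence (iterates escaping [alpha, 0.5)) is
a reported regime, not an exception.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .canonical import EquivalenceSpec, MCConfig
from .power import make_kernel
from .size_search import NullMaximizer, find_lambda

__all__ = ["AdjustmentResult", "existence_bound", "alpha_star", "fixed_point_inner"]

# iterates may dip this far below alpha before we call it divergence
# (Monte Carlo noise can push a near-converged iterate slightly under)
_LEVEL_SLACK = 1e-3


@dataclasses.dataclass(frozen=True)
class AdjustmentResult:
    """Outcome of the level adjustment.

    ``alpha_star`` is the corrected level (equal to the nominal alpha when the
    adjustment does not exist, so downstream code can always read it);
    ``inner_trace`` holds the level iterates of each outer round for
    convergence diagnostics.
    """

    alpha_star: float
    exists: bool
    outer_iters: int
    inner_trace: tuple[tuple[float, ...], ...]
    lam_final: NullMaximizer | None
    omega_kind: str = "population"
    notes: tuple[str, ...] = ()

    @property
    def converged(self) -> bool:
        return self.exists


def existence_bound(m: int, alpha: float, c: float) -> float:
    """Largest sigma_max for which the adjustment exists under independence.

    Returns 2c / Phi^{-1}(alpha^{1/m} + 1/2); requires alpha < (1/2)^m so the
    quantile argument stays below 1.  Under nearly perfect dependence the
    m = 1 bound applies instead, so this is the conservative end of the
    dependence range.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not c > 0:
        raise ValueError("c must be positive")
    if alpha >= 0.5**m:
        raise ValueError(
            f"existence bound requires alpha < (1/2)^m = {0.5 ** m:g}, got {alpha}"
        )
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 2.0 * c / stats.norm.ppf(alpha ** (1.0 / m) + 0.5)


def _noise_slack(kernel, alpha: float, lam: np.ndarray) -> float:
    """How far below alpha an iterate may dip before we call it divergence."""
    if getattr(kernel, "is_stochastic", False):
        _, se = kernel.power_se(alpha, lam)
        return max(_LEVEL_SLACK, 4.0 * se)
    return _LEVEL_SLACK


def _inner_iteration(
    kernel,
    alpha0: float,
    lam: np.ndarray,
    alpha: float,
    tol_inner: float,
    max_inner: int,
    slack: float = _LEVEL_SLACK,
):
    """Damped fixed-point iteration at frozen lambda; returns (level, trace, ok)."""
    trace = [float(alpha0)]
    a = float(alpha0)
    for _ in range(max_inner):
        p = kernel.power(a, lam)
        a_new = a + alpha - p
        if a_new >= 0.5 or a_new < alpha - slack:
            trace.append(float(a_new))
            return a, trace, False
        trace.append(float(a_new))
        done = abs(a_new - a) < tol_inner
        a = a_new
        if done:
            return max(a, alpha), trace, True
    return a, trace, False


def fixed_point_inner(
    alpha0: float,
    lam,
    sigma_mat,
    nu: int | None,
    spec: EquivalenceSpec,
    mc: MCConfig | None = None,
    tol_inner: float = 1e-4,
    max_inner: int = 50,
    *,
    kernel=None,
):
    """Run the inner fixed point with lambda frozen; returns (level, trace, ok).

    Exposed mainly for diagnostics: the trace exhibits geometric decay of the
    successive gaps whenever the map contracts, and a bracketing root-finder
    on gamma -> p(gamma, lam) - alpha must agree with the returned level.
    """
    if kernel is None:
        kernel = make_kernel(sigma_mat, nu, spec, mc=mc)
    if not spec.alpha <= alpha0 < 0.5:
        raise ValueError("alpha0 must lie in [alpha, 0.5)")
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    slack = _noise_slack(kernel, spec.alpha, lam)
    return _inner_iteration(
        kernel, alpha0, lam, spec.alpha, tol_inner, max_inner, slack=slack
    )


def alpha_star(
    sigma_mat,
    nu: int | None,
    spec: EquivalenceSpec,
    mc: MCConfig | None = None,
    tol_inner: float = 1e-4,
    tol_outer: float = 1e-4,
    max_inner: int = 50,
    max_outer: int = 20,
    *,
    omega_kind: str = "population",
    warm_alpha: float | None = None,
    warm_lambda=None,
    lambda_xatol: float = 1e-4,
    lambda_faces=None,
    lambda_window=None,
    kernel=None,
) -> AdjustmentResult:
    """Compute the adjusted level alpha*(Omega) by the recursive algorithm.

    Pass ``nu=None`` for the known-covariance analysis (normal quantiles, one
    deterministic rectangle per evaluation).  ``warm_alpha``/``warm_lambda``
    seed the iteration, which the simulation engine uses to re-adjust from
    each replicate's estimated covariance cheaply.  The same frozen Monte
    Carlo draw set is used for every evaluation within one call.
    """
    if kernel is None:
        kernel = make_kernel(sigma_mat, nu, spec, mc=mc)
    alpha = spec.alpha
    notes: list[str] = []
    traces: list[tuple[float, ...]] = []

    level0 = float(warm_alpha) if warm_alpha is not None else alpha
    level0 = min(max(level0, alpha), 0.5 - 1e-9)
    if warm_lambda is not None:
        lam = NullMaximizer(
            lam=np.asarray(warm_lambda, dtype=float),
            face=int(np.argmax(np.asarray(warm_lambda))),
            attained=np.nan,
        )
    else:
        lam = find_lambda(
            level0, kernel=kernel, xatol=lambda_xatol,
            faces=lambda_faces, free_window=lambda_window,
        )

    slack = _noise_slack(kernel, alpha, lam.lam)
    a_prev: float | None = None
    a0 = level0
    for r in range(1, max_outer + 1):
        a, trace, ok = _inner_iteration(
            kernel, a0, lam.lam, alpha, tol_inner, max_inner, slack=slack
        )
        traces.append(tuple(trace))
        if not ok:
            notes.append(
                f"inner iteration left [alpha, 0.5) or stalled at outer round {r}; "
                "the adjustment does not exist for this covariance"
            )
            return AdjustmentResult(
                alpha_star=alpha,
                exists=False,
                outer_iters=r,
                inner_trace=tuple(traces),
                lam_final=None,
                omega_kind=omega_kind,
                notes=tuple(notes),
            )
        if a_prev is not None and abs(a - a_prev) < tol_outer:
            return AdjustmentResult(
                alpha_star=a,
                exists=True,
                outer_iters=r,
                inner_trace=tuple(traces),
                lam_final=lam,
                omega_kind=omega_kind,
                notes=tuple(notes),
            )
        a_prev = a
        a0 = a
        lam = find_lambda(
            a, kernel=kernel, xatol=lambda_xatol,
            faces=lambda_faces, free_window=lambda_window,
        )

    notes.append(f"no outer convergence within {max_outer} rounds")
    return AdjustmentResult(
        alpha_star=alpha,
        exists=False,
        outer_iters=max_outer,
        inner_trace=tuple(traces),
        lam_final=None,
        omega_kind=omega_kind,
        notes=tuple(notes),
    )
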
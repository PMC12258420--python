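"""Canonical objects for multivariate average-equivalence testing.

Every standard average-equivalence design (paired differences, parallel
groups, 2x2 crossover ignoring period effects) reduces to the same canonical
triple: an estimated mean-difference vector ``theta_hat`` that is m-variate
normal around the true difference ``theta`` with covariance ``Sigma``, and an
independent estimate ``Sigma_hat`` of that covariance with ``nu * Sigma_hat``
Wishart distributed on ``nu`` degrees of freedom.  All tests in this package
consume the triple, so reducing a design to it is the only design-specific
step.

This module holds the canonical containers, the reduction of subject-level
paired data to the triple, CSV readers for the two common layouts, and
synthetic generators used throughout the test battery and the simulation
engine.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd


class DegenerateCovarianceError(ValueError):
    """Raised when a covariance matrix is singular or not positive definite."""


def _validate_pd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, rtol=1e-10, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        # fail, don't repair: silent jitter would change test sizes
        raise DegenerateCovarianceError(
            f"{name} is not positive definite (Cholesky failed)"
        ) from exc
    return mat


@dataclasses.dataclass(frozen=True)
class CanonicalModel:
    """Observed canonical triple (theta_hat, Sigma_hat, nu).

    Parameters
    ----------
    theta_hat
        Estimated mean differences on the log scale, length m.
    sigma_hat_mat
        Estimated m x m covariance of ``theta_hat`` (i.e. of the *mean*
        vector, not of individual observations).  Must be symmetric positive
        definite.
    nu
        Degrees of freedom of the Wishart law of ``nu * sigma_hat_mat``.
    outcome_names
        Optional outcome labels, e.g. ``("auc", "cmax")``.
    notes
        Free-form diagnostics recorded during construction.
    """

    theta_hat: np.ndarray
    sigma_hat_mat: np.ndarray
    nu: int
    outcome_names: tuple[str, ...] | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta_hat, dtype=float))
        mat = _validate_pd(self.sigma_hat_mat, "sigma_hat_mat")
        if theta.shape[0] != mat.shape[0]:
            raise ValueError(
                f"theta_hat has length {theta.shape[0]} but sigma_hat_mat is "
                f"{mat.shape[0]}x{mat.shape[1]}"
            )
        if int(self.nu) < 1:
            raise ValueError("nu must be a positive integer")
        if self.outcome_names is not None and len(self.outcome_names) != theta.shape[0]:
            raise ValueError("outcome_names length does not match theta_hat")
        object.__setattr__(self, "theta_hat", theta)
        object.__setattr__(self, "sigma_hat_mat", mat)
        object.__setattr__(self, "nu", int(self.nu))
        if self.outcome_names is not None:
            object.__setattr__(self, "outcome_names", tuple(self.outcome_names))
        object.__setattr__(self, "notes", tuple(self.notes))

    @property
    def m(self) -> int:
        return self.theta_hat.shape[0]

    @property
    def sigma_hat_j(self) -> np.ndarray:
        """Per-outcome standard errors, sqrt of the diagonal of sigma_hat_mat."""
        return np.sqrt(np.diag(self.sigma_hat_mat))

    def to_dict(self) -> dict:
        d = {
            "theta_hat": self.theta_hat.tolist(),
            "sigma_hat": self.sigma_hat_mat.tolist(),
            "nu": self.nu,
        }
        if self.outcome_names is not None:
            d["outcome_names"] = list(self.outcome_names)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CanonicalModel":
        return cls(
            theta_hat=np.asarray(d["theta_hat"], dtype=float),
            sigma_hat_mat=np.asarray(d["sigma_hat"], dtype=float),
            nu=int(d["nu"]),
            outcome_names=tuple(d["outcome_names"]) if "outcome_names" in d else None,
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "CanonicalModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclasses.dataclass(frozen=True)
class PopulationModel:
    """True mean differences ``theta`` and true covariance ``Sigma`` of theta_hat."""

    theta: np.ndarray
    sigma_mat: np.ndarray

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        mat = _validate_pd(self.sigma_mat, "sigma_mat")
        if theta.shape[0] != mat.shape[0]:
            raise ValueError("theta and sigma_mat dimensions differ")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "sigma_mat", mat)

    @property
    def m(self) -> int:
        return self.theta.shape[0]

    @property
    def sigma_j(self) -> np.ndarray:
        return np.sqrt(np.diag(self.sigma_mat))

    @property
    def rho(self) -> np.ndarray:
        """Correlation matrix implied by sigma_mat."""
        s = self.sigma_j
        return self.sigma_mat / np.outer(s, s)


@dataclasses.dataclass(frozen=True)
class EquivalenceSpec:
    """Symmetric equivalence margin and nominal significance level.

    ``c`` is the half-width of the log-scale equivalence region (-c, c); the
    regulatory default log(1.25) corresponds to 0.80-1.25 ratio limits.
    """

    c: float = math.log(1.25)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("margin c must be positive")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclasses.dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings for the Wishart integration of the power function."""

    n_wishart_draws: int = 10_000
    seed: int | None = None
    crn: bool = True  # reuse one frozen draw set across level evaluations
    rect_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_wishart_draws < 1:
            raise ValueError("n_wishart_draws must be >= 1")
        if not self.rect_tol > 0:
            raise ValueError("rect_tol must be positive")


# ---------------------------------------------------------------------------
# reductions and generators
# ---------------------------------------------------------------------------

def from_paired_differences(
    d, *, nu: int | None = None, outcome_names: tuple[str, ...] | None = None
) -> CanonicalModel:
    """Reduce an n x m table of within-subject log-scale differences.

    ``theta_hat`` is the column-mean vector, ``sigma_hat_mat`` the unbiased
    sample covariance of the rows divided by n (the covariance of the mean),
    and ``nu = n - 1`` unless overridden for a design-specific ANOVA.
    """
    if isinstance(d, pd.DataFrame):
        if outcome_names is None:
            outcome_names = tuple(str(cn) for cn in d.columns)
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("paired differences must form a 2-D n x m table")
    n, m = arr.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got n={n}")
    if np.isnan(arr).any():
        raise ValueError("missing cells are not supported")
    theta_hat = arr.mean(axis=0)
    samp_cov = np.atleast_2d(np.cov(arr, rowvar=False, ddof=1))
    sigma_hat_mat = samp_cov / n
    notes: list[str] = []
    if n <= m:
        notes.append(
            f"n={n} <= m={m}: the Wishart density of nu*Sigma_hat is degenerate"
        )
    try:
        _validate_pd(sigma_hat_mat, "sample covariance / n")
    except DegenerateCovarianceError:
        raise
    return CanonicalModel(
        theta_hat=theta_hat,
        sigma_hat_mat=sigma_hat_mat,
        nu=(n - 1) if nu is None else nu,
        outcome_names=outcome_names,
        notes=tuple(notes),
    )


def synthesize_canonical(
    pop: PopulationModel,
    nu: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CanonicalModel:
    """Draw one canonical triple from the population model.

    theta_hat ~ N_m(theta, Sigma) and nu * Sigma_hat ~ Wishart(nu, Sigma),
    drawn independently.  Requires nu >= m so the Wishart draw is positive
    definite almost surely.
    """
    from ._wishart import wishart_matrices

    if nu < pop.m:
        raise DegenerateCovarianceError(
            f"nu={nu} < m={pop.m}: Wishart draw would be singular"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(pop.sigma_mat)
    theta_hat = pop.theta + chol @ rng.standard_normal(pop.m)
    w = wishart_matrices(rng, nu, chol, size=1)[0]
    return CanonicalModel(theta_hat=theta_hat, sigma_hat_mat=w / nu, nu=nu)


def synthesize_paired_data(
    n: int,
    theta,
    within_cov,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    outcome_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Generate n i.i.d. subject-level difference rows ~ N_m(theta, within_cov).

    Feeding the result to :func:`from_paired_differences` recovers theta and
    within_cov / n up to sampling error of order 1/sqrt(n).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    within_cov = _validate_pd(within_cov, "within_cov")
    m = theta.shape[0]
    if n < m + 1:
        raise ValueError(f"need n >= m+1 rows, got n={n}, m={m}")
    if rng is None:
        rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(within_cov)
    rows = theta + rng.standard_normal((n, m)) @ chol.T
    if outcome_names is None:
        outcome_names = tuple(f"d{j + 1}" for j in range(m))
    return pd.DataFrame(rows, columns=list(outcome_names))


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def read_differences_csv(path: str | Path) -> pd.DataFrame:
    """Wide layout: header of outcome names, one row of log-differences per subject."""
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError("empty differences table")
    return df.astype(float)


def read_crossover_csv(path: str | Path) -> pd.DataFrame:
    """Long layout: columns subject, treatment (T/R), outcome, value.

    Pairs T and R per subject and outcome, applies the natural log to the raw
    values and returns the wide table of log(T) - log(R) differences.
    """
    df = pd.read_csv(path)
    required = {"subject", "treatment", "outcome", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV is missing columns: {sorted(missing)}")
    bad = set(df["treatment"].unique()) - {"T", "R"}
    if bad:
        raise ValueError(f"treatment codes must be 'T' or 'R', found {sorted(bad)}")
    if (df["value"] <= 0).any():
        raise ValueError("values must be positive to apply the log transform")
    wide = df.pivot_table(
        index=["subject", "outcome"], columns="treatment", values="value",
        aggfunc="first",
    )
    if "T" not in wide.columns or "R" not in wide.columns or wide[["T", "R"]].isna().any().any():
        raise ValueError("every subject/outcome needs both a T and an R value")
    diff = np.log(wide["T"]) - np.log(wide["R"])
    out = diff.unstack("outcome")
    out.columns.name = None
    return out.reset_index(drop=True)
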
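"""Vectorised Wishart sampling via the Bartlett decomposition.

If L is the lower Cholesky factor of the scale matrix and A is lower
triangular with A[j,j]^2 ~ chi-square(nu - j) (0-indexed) and standard-normal
strict lower entries, then W = (L A)(L A)^T ~ Wishart(nu, L L^T).  Only the
diagonal of W is needed by the power kernel, which the dedicated helper
exploits.
"""

from __future__ import annotations

import numpy as np


def _bartlett_factors(rng: np.random.Generator, nu: int, m: int, size: int) -> np.ndarray:
    if nu < m:
        raise ValueError(f"nu={nu} < m={m}: Wishart draws would be singular")
    a = np.zeros((size, m, m))
    for j in range(m):
        a[:, j, j] = np.sqrt(rng.chisquare(nu - j, size=size))
    if m > 1:
        idx = np.tril_indices(m, k=-1)
        a[:, idx[0], idx[1]] = rng.standard_normal((size, idx[0].size))
    return a


def wishart_matrices(
    rng: np.random.Generator, nu: int, chol: np.ndarray, size: int
) -> np.ndarray:
    """Draw ``size`` matrices W ~ Wishart(nu, chol @ chol.T), shape (size, m, m)."""
    m = chol.shape[0]
    a = _bartlett_factors(rng, nu, m, size)
    la = np.einsum("ij,bjk->bik", chol, a)
    return np.einsum("bik,bjk->bij", la, la)


def wishart_sqrt_diag(
    rng: np.random.Generator, nu: int, chol: np.ndarray, size: int
) -> np.ndarray:
    """sqrt(diag(W / nu)) for ``size`` Wishart(nu, chol @ chol.T) draws, shape (size, m)."""
    m = chol.shape[0]
    a = _bartlett_factors(rng, nu, m, size)
    la = np.einsum("ij,bjk->bik", chol, a)
    return np.sqrt((la**2).sum(axis=2) / nu)
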
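"""Leroux conditional autoregressive (CAR) linear algebra.

The Leroux prior for a spatial surface phi is the zero-mean multivariate
Gaussian N(0, tau2 * Q(rho, W)^{-1}) with sparse precision

    Q(rho, W) = rho * (diag(W1) - W) + (1 - rho) * I,   rho in [0, 1),

which interpolates between independence (rho = 0) and the intrinsic CAR
model (rho -> 1).  Because diag(W1) - W is the graph Laplacian, its
eigenvalues lambda_i are non-negative and

    log det Q = sum_i log(rho * lambda_i + 1 - rho),

so a single eigendecomposition per neighbourhood matrix makes the
log-density cheap to evaluate for any (rho, tau2) during MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PrecisionStructure",
    "leroux_precision",
    "car_logdensity",
    "full_conditional",
    "partial_correlation",
]

LOG2PI = float(np.log(2.0 * np.pi))


def _as_sparse_W(W) -> sp.csr_matrix:
    if sp.issparse(W):
        return sp.csr_matrix(W)
    return sp.csr_matrix(np.asarray(W, dtype=float))


@dataclass
class PrecisionStructure:
    """Cached pieces of a Leroux precision ``tau2^{-1} Q(rho, W)``."""

    W: sp.csr_matrix
    rho: float
    tau2: float
    rowsums: np.ndarray = field(default=None)  # type: ignore[assignment]
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]
    laplacian: sp.csr_matrix = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = _as_sparse_W(self.W)
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")
        if self.rowsums is None:
            self.rowsums = np.asarray(self.W.sum(axis=1)).ravel()
        if self.laplacian is None:
            self.laplacian = sp.csr_matrix(sp.diags(self.rowsums) - self.W)
        if self.eigenvalues is None:
            self.eigenvalues = np.linalg.eigvalsh(self.laplacian.toarray())

    @property
    def n(self) -> int:
        return self.W.shape[0]


def leroux_precision(rho: float, W, sparse: bool = False):
    """The Leroux precision ``Q(rho, W) = rho (diag(W1) - W) + (1 - rho) I``.

    Diagonal entries are ``rho * rowsum_i + 1 - rho`` and off-diagonals
    ``-rho * w_ij``; the matrix is positive definite for every
    ``rho in [0, 1)``.  Returns a dense array unless ``sparse=True``.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    W = _as_sparse_W(W)
    d = np.asarray(W.sum(axis=1)).ravel()
    Q = rho * (sp.diags(d) - W) + (1.0 - rho) * sp.identity(W.shape[0])
    Q = sp.csr_matrix(Q)
    return Q if sparse else Q.toarray()


def car_logdensity(phi: np.ndarray, ps: PrecisionStructure) -> float:
    """Log density of ``phi ~ N(0, tau2 Q(rho, W)^{-1})``.

    The log-determinant comes from the cached Laplacian eigenvalues and the
    quadratic form from sparse matrix-vector products, so no dense
    factorisation is performed.
    """
    phi = np.asarray(phi, dtype=float)
    n = ps.n
    if phi.shape[-1] != n and phi.shape[0] != n:
        raise ValueError("phi length does not match precision dimension")
    rho, tau2 = ps.rho, ps.tau2
    logdet = float(np.log(rho * ps.eigenvalues + (1.0 - rho)).sum())
    quad = rho * float(phi @ (ps.laplacian @ phi)) + (1.0 - rho) * float(phi @ phi)
    return -0.5 * n * (LOG2PI + np.log(tau2)) + 0.5 * logdet - quad / (2.0 * tau2)


def full_conditional(i: int, phi: np.ndarray, ps: PrecisionStructure) -> Tuple[float, float]:
    """Mean and variance of ``phi_i`` given every other component.

    mean = rho * sum_j w_ij phi_j / (rho * d_i + 1 - rho)
    var  = tau2 / (rho * d_i + 1 - rho)

    An isolated unit (``d_i = 0``, e.g. a singleton cluster) falls back to
    the proper N(0, tau2 / (1 - rho)); this is why rho is kept strictly
    below one throughout.
    """
    phi = np.asarray(phi, dtype=float)
    if not (0 <= i < ps.n):
        raise IndexError("area index out of range")
    denom = ps.rho * ps.rowsums[i] + (1.0 - ps.rho)
    row = ps.W.getrow(i)
    neigh_sum = float(phi[row.indices].sum()) if row.nnz else 0.0
    return ps.rho * neigh_sum / denom, ps.tau2 / denom


def partial_correlation(i: int, j: int, ps: PrecisionStructure) -> float:
    """Partial correlation of ``(phi_i, phi_j)`` given the remaining effects.

    Zero whenever ``w_ij = 0``: severed borders translate directly into
    conditional independence.
    """
    if i == j:
        raise ValueError("partial correlation requires i != j")
    wij = float(ps.W[i, j])
    di = ps.rho * ps.rowsums[i] + (1.0 - ps.rho)
    dj = ps.rho * ps.rowsums[j] + (1.0 - ps.rho)
    return ps.rho * wij / float(np.sqrt(di * dj))
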
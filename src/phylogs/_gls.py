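"""Shared generalized-least-squares numerics.

Both the phylogenetic-signal and PGLS stages reduce to ML estimation of a
Gaussian model ``y ~ N(X beta, sigma^2 V)`` with ``V`` fixed.  Everything is
done through the Cholesky factor of ``V`` (whitening), with a tiny diagonal
jitter retried when ``V`` is numerically singular — e.g. duplicate rows from
zero-length terminal branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

JITTER = 1e-10


class SingularCovarianceError(np.linalg.LinAlgError):
    """V not positive definite even after diagonal regularization."""


@dataclass
class GLSCore:
    beta: np.ndarray
    sigma2_ml: float          # r' V^-1 r / n
    sigma2_unbiased: float    # r' V^-1 r / (n - p)
    loglik: float             # ML log-likelihood at (beta, sigma2_ml)
    cov_beta: np.ndarray      # sigma2_unbiased * (X' V^-1 X)^-1
    logdet_v: float
    n: int
    p: int


def chol_with_jitter(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of V, adding ``JITTER`` to the diagonal on failure."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        try:
            return linalg.cholesky(V + JITTER * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "covariance matrix singular after regularization"
            ) from exc


def gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GLSCore:
    """ML generalized least squares of ``y`` on ``X`` with covariance ``V``.

    Returns estimates, the exact Gaussian log-likelihood at the ML point,
    and the coefficient covariance based on the unbiased residual scale.
    Raises on rank deficiency or ``n <= p``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")

    L = chol_with_jitter(V)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError("design matrix is rank deficient after whitening")

    xtx = Xw.T @ Xw
    beta = linalg.solve(xtx, Xw.T @ yw, assume_a="pos")
    rw = yw - Xw @ beta
    quad = float(rw @ rw)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))

    sigma2_ml = quad / n
    if sigma2_ml <= 0 or not np.isfinite(sigma2_ml):
        raise ValueError("degenerate trait: zero residual variance")
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet_v + n)
    sigma2_unb = quad / (n - p)
    cov_beta = sigma2_unb * linalg.inv(xtx)
    return GLSCore(
        beta=beta,
        sigma2_ml=sigma2_ml,
        sigma2_unbiased=sigma2_unb,
        loglik=float(loglik),
        cov_beta=cov_beta,
        logdet_v=logdet_v,
        n=n,
        p=p,
    )
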
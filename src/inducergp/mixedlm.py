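"""Eigen-based profiled REML for one-variance-component mixed models.

Shared numerical core for the MLM GWAS scan (polygenic covariance K) and
rrBLUP (marker covariance Z Z').  The model is

    y = W b + g + e,   g ~ N(0, s2_u K),   e ~ N(0, s2_e I)

With K = U diag(d) U' fixed, rotating by U' diagonalises the covariance:
Var(U'y) = s2_u diag(d + lambda), lambda = s2_e / s2_u.  The restricted
likelihood then profiles to a 1-D function of lambda, optimised by a
bounded Brent search on log10(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["EigenREML", "eigen_reml"]


@dataclass
class EigenREML:
    lam: float            # s2_e / s2_u
    s2_u: float
    s2_e: float
    beta: np.ndarray      # GLS fixed effects
    U: np.ndarray         # eigenvectors of K
    d: np.ndarray         # eigenvalues of K (clipped at 0)
    loglik: float
    converged: bool


def eigen_reml(y: np.ndarray, W: np.ndarray, K: np.ndarray | None = None,
               eig: tuple | None = None,
               log10_bounds: tuple = (-8.0, 8.0)) -> EigenREML:
    """Profiled REML estimate of the variance ratio.

    Either `K` or a precomputed eigendecomposition ``eig=(d, U)`` must be
    given; ``K=None`` means the identity (which collapses the GLS to OLS).
    """
    y = np.asarray(y, float)
    W = np.atleast_2d(np.asarray(W, float))
    if W.shape[0] != y.shape[0]:
        W = W.T
    n, p = W.shape
    if eig is not None:
        d, U = eig
    elif K is None:
        d, U = np.ones(n), np.eye(n)
    else:
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W

    def profile(lam):
        w = 1.0 / (d + lam)
        A = Wt * w[:, None]
        XtVX = Wt.T @ A
        beta = np.linalg.solve(XtVX, A.T @ yt)
        r = yt - Wt @ beta
        q = float(np.sum(r * r * w))
        return beta, q, XtVX

    def neg_ll(log10_lam):
        lam = 10.0 ** log10_lam
        _, q, XtVX = profile(lam)
        if q <= 0:
            return -np.inf
        s2u = q / (n - p)
        sign, logdetX = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * np.log(s2u) + np.sum(np.log(d + lam))
                      + logdetX + (n - p))

    res = minimize_scalar(neg_ll, bounds=log10_bounds, method="bounded",
                          options={"xatol": 1e-9, "maxiter": 500})
    lam = float(10.0 ** res.x)
    beta, q, _ = profile(lam)
    s2u = q / (n - p)
    return EigenREML(lam, s2u, lam * s2u, beta, U, d,
                     loglik=-float(res.fun), converged=bool(res.success))
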
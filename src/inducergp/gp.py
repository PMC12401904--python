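"""Genomic prediction models.

Single-trait models follow

    y = mu + X b + Z u + e

with X the (possibly empty) incidence matrix of GWAS-detected fixed SNPs
and Z the genome-wide markers.  :class:`RidgeGP` (rrBLUP) gives every
marker a common variance — equivalent to GBLUP under a VanRaden genomic
relationship matrix — while :class:`BayesBGP` gives markers their own
variances and lets a proportion of them drop out entirely.

Any single-trait solver lifts to multiple traits through
:class:`MultiTraitGP`: the trait matrix is centered, scaled, and rotated
by the right singular vectors V of its SVD; the base model is fitted
independently to each rotated column Y* = Y V, and effects and
predictions are rotated back with V'.

Tree-based learners (Random Forest, xGBoost) are thin adapters over
scikit-learn and xgboost with a small seeded inner-CV tuning grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import eigen_reml

__all__ = [
    "RidgeGP",
    "RidgeGPResults",
    "BayesBGP",
    "BayesBResults",
    "MultiTraitGP",
    "MultiTraitResults",
    "TreeModelConfig",
    "fit_rrblup",
    "fit_bayesb",
    "fit_multitrait",
    "fit_tree_model",
    "predict_gv",
]


def _prep_fixed(X, n):
    """Validate / reduce the fixed-SNP design; returns (X, kept_columns)."""
    if X is None or (hasattr(X, "shape") and X.shape[-1] == 0) or (
        isinstance(X, (list, tuple)) and len(X) == 0
    ):
        return None, []
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        X = X.T
    W = np.hstack([np.ones((n, 1)), X])
    from scipy.linalg import qr
    _, R, piv = qr(W, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(W.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    aliased = set(piv[rank:])
    keep = [j for j in range(X.shape[1]) if (j + 1) not in aliased]
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(keep)} aliased fixed-SNP columns")
        X = X[:, keep]
    return X, keep


def _align_fixed(X_new, b, kept, n_orig):
    """Subset a prediction-time fixed-SNP matrix to the columns that
    survived aliasing during the fit."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] == len(b):
        return X_new
    if n_orig and X_new.shape[1] == n_orig:
        return X_new[:, kept]
    raise ValueError(
        f"fixed-SNP mismatch: fit kept {len(b)} of {n_orig} columns, "
        f"got {X_new.shape[1]}"
    )


@dataclass
class RidgeGPResults:
    """rrBLUP fit: intercept, fixed SNP effects b, random marker effects u."""

    mu: float
    b: np.ndarray
    u: np.ndarray
    sigma2_m: float
    sigma2_e: float
    lam: float                      # sigma2_e / sigma2_m
    z_means: np.ndarray
    marker_ids: list = field(default_factory=list)
    fixed_snp_ids: list = field(default_factory=list)
    fixed_kept: list = field(default_factory=list)   # surviving column idx
    fixed_n_orig: int = 0                            # columns before aliasing

    def predict(self, Z_new, X_new=None) -> np.ndarray:
        """Genotypic values mu + X_new b + Z_new u for new lines."""
        Z_new = np.atleast_2d(np.asarray(Z_new, float))
        if Z_new.shape[1] != self.u.shape[0]:
            raise ValueError(
                f"marker-set mismatch: fit has {self.u.shape[0]} markers, "
                f"got {Z_new.shape[1]}"
            )
        gv = self.mu + (Z_new - self.z_means) @ self.u
        if len(self.b):
            if X_new is None:
                raise ValueError("fit has fixed SNPs; X_new required")
            X_new = _align_fixed(X_new, self.b, self.fixed_kept,
                                 self.fixed_n_orig)
            gv = gv + X_new @ self.b
        return gv

    def summary(self) -> str:
        return (
            "rrBLUP fit\n"
            f"  markers (random): {self.u.shape[0]}\n"
            f"  fixed SNPs:       {len(self.b)}\n"
            f"  mu:               {self.mu:.4f}\n"
            f"  sigma2_marker:    {self.sigma2_m:.6g}\n"
            f"  sigma2_residual:  {self.sigma2_e:.6g}\n"
            f"  lambda (e/m):     {self.lam:.6g}"
        )


class RidgeGP:
    """Ridge-regression BLUP of marker effects (common marker variance).

    The variance ratio lambda = sigma2_e / sigma2_m is estimated by REML
    through the eigendecomposition of Z Z' (markers column-centered), and
    u = Z' (Z Z' + lambda I)^-1 (y - W beta) solves the mixed-model
    equations.  Deterministic.
    """

    def __init__(self, y, Z, X=None, marker_ids=None, fixed_snp_ids=None):
        self.y = np.asarray(y, float)
        self.Z = np.atleast_2d(np.asarray(Z, float))
        if self.y.ndim != 1 or self.Z.shape[0] != self.y.shape[0]:
            raise ValueError("y and Z are not aligned")
        if self.y.shape[0] < 2:
            raise ValueError("need at least 2 lines")
        self._n_orig = 0 if X is None else np.atleast_2d(np.asarray(X, float)).shape[-1]
        self.X, self._kept = _prep_fixed(X, self.y.shape[0])
        self.marker_ids = list(marker_ids) if marker_ids is not None else []
        ids = list(fixed_snp_ids) if fixed_snp_ids is not None else []
        self.fixed_snp_ids = [ids[j] for j in self._kept] if ids else []

    def fit(self) -> RidgeGPResults:
        n, m = self.Z.shape
        z_means = self.Z.mean(axis=0)
        Zc = self.Z - z_means
        W = np.ones((n, 1)) if self.X is None else np.hstack([np.ones((n, 1)), self.X])
        # degenerate: no residual variation after the fixed part
        resid0 = self.y - W @ np.linalg.lstsq(W, self.y, rcond=None)[0]
        if float(resid0 @ resid0) / n < 1e-14 * max(1.0, float(self.y @ self.y) / n):
            beta = np.linalg.lstsq(W, self.y, rcond=None)[0]
            return RidgeGPResults(float(beta[0]), beta[1:], np.zeros(m),
                                  0.0, 0.0, np.inf, z_means,
                                  self.marker_ids, self.fixed_snp_ids,
                                  self._kept, self._n_orig)
        K = Zc @ Zc.T
        fit = eigen_reml(self.y, W, K=K)
        resid = self.y - W @ fit.beta
        Ur = fit.U.T @ resid
        u = Zc.T @ (fit.U @ (Ur / (fit.d + fit.lam)))
        return RidgeGPResults(float(fit.beta[0]), fit.beta[1:], u,
                              float(fit.s2_u), float(fit.s2_e), float(fit.lam),
                              z_means, self.marker_ids, self.fixed_snp_ids,
                              self._kept, self._n_orig)


def fit_rrblup(y, Z, X=None, **kw) -> RidgeGPResults:
    return RidgeGP(y, Z, X, **kw).fit()


# ---------------------------------------------------------------------------
# BayesB


@dataclass
class BayesBResults:
    mu: float
    b: np.ndarray
    u: np.ndarray                   # posterior-mean marker effects E[delta u]
    inclusion_prob: np.ndarray
    pi: float                       # posterior-mean exclusion probability
    sigma2_e: float
    s2e_chain: np.ndarray
    burn_in: int
    iterations: int
    seed: int
    z_means: np.ndarray = None
    marker_ids: list = field(default_factory=list)
    fixed_snp_ids: list = field(default_factory=list)
    fixed_kept: list = field(default_factory=list)
    fixed_n_orig: int = 0

    def predict(self, Z_new, X_new=None) -> np.ndarray:
        Z_new = np.atleast_2d(np.asarray(Z_new, float))
        if Z_new.shape[1] != self.u.shape[0]:
            raise ValueError("marker-set mismatch in BayesB prediction")
        gv = self.mu + (Z_new - self.z_means) @ self.u
        if len(self.b):
            if X_new is None:
                raise ValueError("fit has fixed SNPs; X_new required")
            X_new = _align_fixed(X_new, self.b, self.fixed_kept,
                                 self.fixed_n_orig)
            gv = gv + X_new @ self.b
        return gv

    def summary(self) -> str:
        return (
            "BayesB fit (Gibbs posterior means)\n"
            f"  markers: {self.u.shape[0]}, fixed SNPs: {len(self.b)}\n"
            f"  chain: {self.iterations} iterations, {self.burn_in} burn-in, "
            f"seed {self.seed}\n"
            f"  mu: {self.mu:.4f}  pi (exclusion): {self.pi:.3f}\n"
            f"  sigma2_residual: {self.sigma2_e:.6g}"
        )


class BayesBGP:
    """BayesB: marker-specific variances with a point mass at zero.

    Hyperpriors: pi ~ Beta(kappa pi0, kappa (1 - pi0)) with prior-mean
    exclusion pi0 = 0.95; marker variances scaled-inverse-chi-square with
    df 5 and scale chosen so the prior genomic variance is half the
    phenotypic variance; residual variance likewise.  `fix_pi` pins the
    mixture probability (fix_pi=0 includes every marker) and
    `common_marker_variance` forces a single shared marker variance —
    together these reduce the model to a Bayesian ridge for validation
    against rrBLUP.
    """

    def __init__(self, y, Z, X=None, burn_in: int = 1000, iterations: int = 6000,
                 pi0: float = 0.95, kappa: float = 10.0, df_marker: float = 5.0,
                 df_resid: float = 5.0, fix_pi: float | None = None,
                 common_marker_variance: bool = False,
                 marker_ids=None, fixed_snp_ids=None):
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if not 0 <= pi0 <= 1:
            raise ValueError("pi0 must be in [0, 1]")
        self.y = np.asarray(y, float)
        self.Z = np.atleast_2d(np.asarray(Z, float))
        if self.Z.shape[0] != self.y.shape[0]:
            raise ValueError("y and Z are not aligned")
        self._n_orig = 0 if X is None else np.atleast_2d(np.asarray(X, float)).shape[-1]
        self.X, self._kept = _prep_fixed(X, self.y.shape[0])
        self.burn_in, self.iterations = int(burn_in), int(iterations)
        self.pi0, self.kappa = float(pi0), float(kappa)
        self.df_marker, self.df_resid = float(df_marker), float(df_resid)
        self.fix_pi = -1.0 if fix_pi is None else float(fix_pi)
        self.common_var = bool(common_marker_variance)
        self.marker_ids = list(marker_ids) if marker_ids is not None else []
        ids = list(fixed_snp_ids) if fixed_snp_ids is not None else []
        self.fixed_snp_ids = [ids[j] for j in self._kept] if ids else []

    def fit(self, seed: int = 0) -> BayesBResults:
        from ._bayesb import gibbs

        n, m = self.Z.shape
        z_means = self.Z.mean(axis=0)
        Zc = np.ascontiguousarray((self.Z - z_means).T)   # markers x lines
        W = np.ones((n, 1)) if self.X is None else np.hstack([np.ones((n, 1)), self.X])
        zz = np.einsum("ji,ji->j", Zc, Zc)
        ww = np.einsum("ij,ij->j", W, W)
        vy = float(np.var(self.y))
        if vy <= 0:
            vy = 1e-8
        sum_zvar = float(np.sum(zz) / n)
        incl = max(1.0 - (self.pi0 if self.fix_pi < 0 else self.fix_pi), 1e-3)
        nu = self.df_marker
        S0 = 0.5 * vy * (nu - 2.0) / (nu * incl * max(sum_zvar, 1e-12))
        nu_e = self.df_resid
        Se = 0.5 * vy * (nu_e - 2.0) / nu_e
        out = gibbs(self.y, W, Zc, zz, ww, self.iterations, self.burn_in,
                    nu, S0, nu_e, Se, self.pi0, self.kappa, self.fix_pi,
                    self.common_var, int(seed))
        sum_alpha, sum_u, sum_delta, sum_pi, s2e_chain, err = out
        if err >= 0:
            raise RuntimeError(f"BayesB chain diverged at iteration {err}")
        n_keep = self.iterations - self.burn_in
        alpha = sum_alpha / n_keep
        return BayesBResults(
            mu=float(alpha[0]), b=alpha[1:], u=sum_u / n_keep,
            inclusion_prob=sum_delta / n_keep, pi=float(sum_pi / n_keep),
            sigma2_e=float(s2e_chain.mean()), s2e_chain=s2e_chain,
            burn_in=self.burn_in, iterations=self.iterations, seed=int(seed),
            z_means=z_means, marker_ids=self.marker_ids,
            fixed_snp_ids=self.fixed_snp_ids,
            fixed_kept=self._kept, fixed_n_orig=self._n_orig,
        )


def fit_bayesb(y, Z, X=None, burn_in=1000, iterations=6000, seed=0, **kw) -> BayesBResults:
    return BayesBGP(y, Z, X, burn_in=burn_in, iterations=iterations, **kw).fit(seed=seed)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    chain = np.asarray(chain, float)
    n = len(chain)
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        return 0.0
    return float((a.mean() - b.mean()) / se)


# ---------------------------------------------------------------------------
# multi-trait SVD wrapper


@dataclass
class MultiTraitResults:
    trait_names: list
    V: np.ndarray                    # t x t right singular vectors
    fits: list                       # per-transformed-trait base results
    b: np.ndarray                    # back-transformed fixed effects (g1 x t)
    u: np.ndarray                    # back-transformed marker effects (g2 x t)
    mu: np.ndarray                   # per-transformed-trait intercepts
    centers: np.ndarray
    scales: np.ndarray
    base: str

    def predict(self, Z_new, X_new=None) -> pd.DataFrame:
        """Per-trait genotypic values for new lines (original trait units)."""
        Z_new = np.atleast_2d(np.asarray(Z_new, float))
        star = np.column_stack(
            [f.predict(Z_new, X_new if len(f.b) else None) for f in self.fits]
        )
        Yhat = star @ self.V.T
        Yhat = Yhat * self.scales + self.centers
        return pd.DataFrame(Yhat, columns=self.trait_names)

    def summary(self) -> str:
        lines = [f"Multi-trait {self.base} fit over {len(self.trait_names)} traits",
                 f"  traits: {', '.join(self.trait_names)}",
                 f"  fixed SNPs: {self.b.shape[0]}  markers: {self.u.shape[0]}"]
        return "\n".join(lines)


class MultiTraitGP:
    """SVD-transform multi-trait wrapper over a single-trait solver.

    Trait columns are centered and scaled to unit variance; the base model
    is fitted to each column of Y* = Y V (V from the SVD of the scaled
    trait matrix, each column oriented so its largest-magnitude entry is
    positive); effects and predictions are back-rotated by V'.
    Requires complete cases for every trait.
    """

    def __init__(self, Y, Z, X=None, base: str = "rrblup", **base_kwargs):
        if isinstance(Y, pd.DataFrame):
            self.trait_names = list(Y.columns)
            Y = Y.to_numpy(float)
        else:
            Y = np.atleast_2d(np.asarray(Y, float))
            self.trait_names = [f"trait{k + 1}" for k in range(Y.shape[1])]
        if Y.shape[1] < 2:
            raise ValueError("multi-trait fit needs at least 2 traits")
        if np.isnan(Y).any():
            raise ValueError(
                "missing trait values: filter to complete cases before a "
                "multi-trait fit"
            )
        if base not in ("rrblup", "bayesb"):
            raise ValueError(f"unknown base model {base!r}")
        self.Y, self.Z, self.X = Y, Z, X
        self.base, self.base_kwargs = base, base_kwargs

    def fit(self, seed: int = 0) -> MultiTraitResults:
        Y = self.Y
        centers = Y.mean(axis=0)
        scales = Y.std(axis=0, ddof=1)
        scales = np.where(scales > 0, scales, 1.0)
        Ys = (Y - centers) / scales
        _, _, Vt = np.linalg.svd(Ys, full_matrices=True)
        V = Vt.T
        for j in range(V.shape[1]):
            i = int(np.argmax(np.abs(V[:, j])))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        Ystar = Ys @ V
        fits = []
        for k in range(Ystar.shape[1]):
            if self.base == "rrblup":
                fits.append(RidgeGP(Ystar[:, k], self.Z, self.X,
                                    **self.base_kwargs).fit())
            else:
                fits.append(BayesBGP(Ystar[:, k], self.Z, self.X,
                                     **self.base_kwargs).fit(seed=seed + k))
        b_star = np.column_stack([f.b for f in fits]) if fits[0].b.size else \
            np.zeros((0, len(fits)))
        u_star = np.column_stack([f.u for f in fits])
        return MultiTraitResults(
            trait_names=self.trait_names, V=V, fits=fits,
            b=b_star @ V.T, u=u_star @ V.T,
            mu=np.array([f.mu for f in fits]),
            centers=centers, scales=scales, base=self.base,
        )


def fit_multitrait(Y, Z, X=None, base="rrblup", seed=0, **kw) -> MultiTraitResults:
    return MultiTraitGP(Y, Z, X, base=base, **kw).fit(seed=seed)


# ---------------------------------------------------------------------------
# tree-based adapters


@dataclass
class TreeModelConfig:
    """Hyperparameter grid/settings for the tree-based adapters."""

    model: str = "rf"                 # "rf" or "xgboost"
    trees: int = 300
    mtry: tuple = (0.1, 0.33, 1.0)    # fraction of features per split (rf)
    min_n: tuple = (2, 5)             # min samples per leaf (rf)
    tree_depth: tuple = (3, 6)        # max depth (xgboost)
    learning_rate: tuple = (0.05, 0.1)
    tuning_budget: int = 8
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("rf", "xgboost"):
            raise ValueError(f"unknown tree model {self.model!r}")
        if self.trees <= 0:
            raise ValueError("trees must be positive")
        for lr in np.atleast_1d(self.learning_rate):
            if not 0 < lr <= 1:
                raise ValueError("learning_rate must be in (0, 1]")


def fit_tree_model(y, Z, config: TreeModelConfig):
    """Seeded inner-CV (MSE) tuning over a small grid; returns the refitted
    best estimator (scikit-learn interface: .predict(Z_new))."""
    from itertools import product

    from sklearn.model_selection import KFold

    y = np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(Z, float))
    if np.ptp(y) == 0:
        class _Const:
            def __init__(self, c):
                self.c = c
            def predict(self, Znew):
                return np.full(np.atleast_2d(Znew).shape[0], self.c)
        return _Const(float(y[0]))

    if config.model == "rf":
        from sklearn.ensemble import RandomForestRegressor
        grid = [
            {"max_features": mf, "min_samples_leaf": mn}
            for mf, mn in product(np.atleast_1d(config.mtry),
                                  np.atleast_1d(config.min_n))
        ]
        def build(params):
            return RandomForestRegressor(
                n_estimators=config.trees, random_state=config.seed,
                n_jobs=1, **params)
    else:
        from xgboost import XGBRegressor
        grid = [
            {"max_depth": int(d), "learning_rate": float(lr)}
            for d, lr in product(np.atleast_1d(config.tree_depth),
                                 np.atleast_1d(config.learning_rate))
        ]
        def build(params):
            return XGBRegressor(
                n_estimators=config.trees, random_state=config.seed,
                n_jobs=1, verbosity=0, **params)

    grid = grid[: config.tuning_budget]
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    best, best_mse = None, np.inf
    for params in grid:
        mse = 0.0
        for tr, te in kf.split(Z):
            est = build(params)
            est.fit(Z[tr], y[tr])
            pred = est.predict(Z[te])
            mse += float(np.mean((pred - y[te]) ** 2))
        if mse < best_mse:
            best, best_mse = params, mse
    est = build(best)
    est.fit(Z, y)
    return est


def predict_gv(fit, Z_new, X_new=None):
    """Predicted genotypic values from any fitted results object."""
    return fit.predict(Z_new, X_new) if hasattr(fit, "predict") else None
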
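"""Phenotype adjustment for unbalanced multi-year field trials.

Plot records ``(genotype, year, block, trait, value)`` are adjusted with a
fixed-effects linear model

    y_ijk = mu + year_i + block(year)_j(i) + genotype_k + e_ijk

whose per-genotype estimated marginal means (equal weights across year and
block-in-year levels) are the BLUE values used as responses in genomic
prediction.  A companion mixed model with genotype random estimates the
genetic and non-genetic variance components by profiled REML, from which
the entry-mean reliability

    i2 = sigma2_g / (sigma2_g + sigma2_e / r)

is computed, with r the harmonic mean number of replicates per genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "validate_records",
    "BlueModel",
    "BlueResults",
    "VarianceComponentModel",
    "VarianceComponentResults",
    "VarianceComponents",
    "fit_blue",
    "blue_table",
    "estimate_variance_components",
    "harmonic_mean_reps",
    "reliability",
]

REQUIRED_COLUMNS = ("genotype", "year", "block", "trait", "value")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    if records.duplicated(subset=["genotype", "year", "block", "trait"]).any():
        raise ValueError("duplicated (genotype, year, block, trait) records")
    if not np.isfinite(records["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    return records


def _trait_records(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return sub.reset_index(drop=True)


def _design(sub: pd.DataFrame, interaction: bool = False):
    """Treatment-coded design matrix: intercept, year, block nested in
    year, genotype (one dropped level per factor); returns the matrix,
    column labels, and the equal-weight marginal-mean base row."""
    years = sorted(sub["year"].unique())
    blocks = sorted(sub["block"].unique())
    genos = sorted(sub["genotype"].unique())
    cols, labels = [np.ones(len(sub))], ["intercept"]
    base = [1.0]
    for y in years[1:]:
        cols.append((sub["year"] == y).to_numpy(float))
        labels.append(f"year[{y}]")
        base.append(1.0 / len(years))
    n_cells = len(years) * len(blocks)
    for y in years:
        for b in blocks[1:]:
            cols.append(((sub["year"] == y) & (sub["block"] == b)).to_numpy(float))
            labels.append(f"block[{y}:{b}]")
            base.append(1.0 / n_cells)
    geno_start = len(cols)
    for g in genos[1:]:
        cols.append((sub["genotype"] == g).to_numpy(float))
        labels.append(f"genotype[{g}]")
        base.append(0.0)
    if interaction:
        for y in years[1:]:
            for g in genos[1:]:
                cols.append(((sub["year"] == y) & (sub["genotype"] == g)).to_numpy(float))
                labels.append(f"year:genotype[{y}:{g}]")
                base.append(0.0)
    X = np.column_stack(cols)
    return X, labels, np.array(base), genos, geno_start


def _drop_aliased(X, labels, base, geno_start):
    """Pivoted-QR rank check; aliased genotype columns are an error,
    aliased year/block cells are dropped (empty design cells)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    aliased = sorted(piv[rank:])
    bad_geno = [labels[i] for i in aliased if labels[i].startswith("genotype[")]
    if bad_geno:
        names = ", ".join(g[len("genotype["):-1] for g in bad_geno)
        raise ValueError(f"confounded design: genotypes aliased with year/block: {names}")
    if aliased:
        warnings.warn(f"dropping {len(aliased)} aliased design columns (empty cells)")
        keep = [i for i in range(X.shape[1]) if i not in aliased]
        return X[:, keep], [labels[i] for i in keep], base[keep]
    return X, labels, base


@dataclass
class BlueResults:
    """Per-genotype BLUE values (estimated marginal means) and the
    underlying OLS coefficient vector."""

    trait: str
    blues: pd.Series
    params: pd.Series

    def summary(self) -> str:
        lines = [f"BLUE estimates — trait {self.trait}",
                 f"genotypes: {len(self.blues)}", "-" * 38]
        lines += [f"{g:<24s}{v:>12.4f}" for g, v in self.blues.items()]
        return "\n".join(lines)


class BlueModel:
    """Fixed-effects model for adjusted genotype means (BLUEs).

    Parameters
    ----------
    records : DataFrame of plot observations (long format).
    trait : trait label to fit.
    year_genotype_interaction : include a year x genotype term
        (sensitivity analysis only; BLUEs then average over years).
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 year_genotype_interaction: bool = False):
        self.records = validate_records(records)
        self.trait = trait
        self.interaction = year_genotype_interaction

    def fit(self) -> BlueResults:
        sub = _trait_records(self.records, self.trait)
        X, labels, base, genos, geno_start = _design(sub, self.interaction)
        X, labels, base = _drop_aliased(X, labels, base, geno_start)
        y = sub["value"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        blues = {}
        for g in genos:
            row = base.copy()
            label = f"genotype[{g}]"
            if label in labels:
                row[labels.index(label)] = 1.0
            if self.interaction:
                for j, lab in enumerate(labels):
                    if lab.startswith("year:genotype[") and lab.endswith(f":{g}]"):
                        row[j] = 1.0 / len(sorted(sub["year"].unique()))
            blues[g] = float(row @ beta)
        return BlueResults(self.trait, pd.Series(blues, name=self.trait),
                           pd.Series(beta, index=labels))


def fit_blue(records: pd.DataFrame, trait: str) -> pd.Series:
    """BLUE (adjusted mean) per genotype for one trait."""
    return BlueModel(records, trait).fit().blues


def blue_table(records: pd.DataFrame) -> pd.DataFrame:
    """Genotype x trait table of BLUEs; genotypes unobserved for a trait
    are NaN in that column."""
    series = {t: fit_blue(records, t) for t in records["trait"].unique()}
    return pd.DataFrame(series)


# ---------------------------------------------------------------------------
# REML variance components


@dataclass
class VarianceComponents:
    sigma2_genetic: float
    sigma2_nongenetic: float
    r_harmonic: float

    def __post_init__(self):
        if self.sigma2_genetic < 0 or self.sigma2_nongenetic < 0:
            raise ValueError("variance components must be non-negative")
        if self.r_harmonic < 1:
            raise ValueError("harmonic mean of replicates must be >= 1")

    @property
    def reliability_i2(self) -> float:
        return reliability(self.sigma2_genetic, self.sigma2_nongenetic,
                           self.r_harmonic)


@dataclass
class VarianceComponentResults:
    trait: str
    sigma2_genetic: float
    sigma2_nongenetic: float
    r_harmonic: float
    loglik: float
    converged: bool
    at_boundary: bool

    @property
    def reliability_i2(self) -> float:
        return reliability(self.sigma2_genetic, self.sigma2_nongenetic,
                           self.r_harmonic)

    def components(self) -> VarianceComponents:
        return VarianceComponents(self.sigma2_genetic, self.sigma2_nongenetic,
                                  self.r_harmonic)

    def summary(self) -> str:
        return (
            f"REML variance components — trait {self.trait}\n"
            f"  sigma2_genetic     {self.sigma2_genetic:.4f}\n"
            f"  sigma2_non-genetic {self.sigma2_nongenetic:.4f}\n"
            f"  harmonic-mean reps {self.r_harmonic:.4f}\n"
            f"  reliability i2     {self.reliability_i2:.4f}\n"
            f"  boundary: {self.at_boundary}, converged: {self.converged}"
        )


class VarianceComponentModel:
    """Mixed model ``value ~ year + block(year) (fixed) + genotype (random)``
    fitted by REML profiled over the genotype/residual variance ratio.

    The genotype incidence structure makes H = I + lambda Z Z' cheap to
    invert through Woodbury (Z'Z is diagonal with the replicate counts), so
    each likelihood evaluation is O(n).  The 1-D profile is optimised by
    Brent search on log10(lambda) to a ratio tolerance of 1e-8.
    """

    def __init__(self, records: pd.DataFrame, trait: str):
        self.records = validate_records(records)
        self.trait = trait

    def fit(self) -> VarianceComponentResults:
        sub = _trait_records(self.records, self.trait)
        genos = sorted(sub["genotype"].unique())
        counts = sub["genotype"].value_counts()
        if len(genos) < 2 or (counts >= 2).sum() < 2:
            raise ValueError("need >= 2 genotypes with >= 2 records each")
        g_idx = sub["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
        n_g = np.bincount(g_idx).astype(float)
        y = sub["value"].to_numpy(float)

        # fixed part: intercept + year + block(year), aliased cells dropped
        X, labels, base, _, geno_start = _design(
            sub.assign(genotype="_pooled_"), interaction=False
        )
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        rank = int(np.sum(diag > tol))
        X = X[:, sorted(piv[:rank])]
        n, p = X.shape

        def Hinv(v, lam):
            # (I + lam Z Z')^{-1} v  via Woodbury; Z'Z = diag(n_g)
            t = np.bincount(g_idx, weights=v, minlength=len(n_g))
            w = lam / (1.0 + lam * n_g)
            return v - (w * t)[g_idx]

        def neg_restricted_ll(log10_lam):
            lam = 10.0 ** log10_lam
            HiX = np.column_stack([Hinv(X[:, j], lam) for j in range(p)])
            XtHiX = X.T @ HiX
            Hiy = Hinv(y, lam)
            beta = np.linalg.solve(XtHiX, X.T @ Hiy)
            r = y - X @ beta
            q = float(r @ Hinv(r, lam))
            s2 = q / (n - p)
            logdetH = float(np.sum(np.log1p(lam * n_g)))
            sign, logdetX = np.linalg.slogdet(XtHiX)
            return 0.5 * ((n - p) * np.log(s2) + logdetH + logdetX + (n - p))

        res = minimize_scalar(neg_restricted_ll, bounds=(-10.0, 10.0),
                              method="bounded",
                              options={"xatol": 1e-9, "maxiter": 500})
        if not res.success:
            raise RuntimeError(
                f"REML did not converge in bracket [1e-10, 1e10]: {res.message}"
            )
        lam = 10.0 ** res.x
        at_boundary = res.x <= -10.0 + 1e-6 or neg_restricted_ll(-10.0) <= res.fun + 1e-10
        if at_boundary:
            lam = 0.0
        # recompute sigma2_e at the optimum
        lam_eval = max(lam, 1e-12)
        HiX = np.column_stack([Hinv(X[:, j], lam_eval) for j in range(p)])
        beta = np.linalg.solve(X.T @ HiX, X.T @ Hinv(y, lam_eval))
        r = y - X @ beta
        s2e = float(r @ Hinv(r, lam_eval)) / (n - p)
        s2g = lam * s2e
        r_h = harmonic_mean_reps(self.records, self.trait)
        return VarianceComponentResults(self.trait, s2g, s2e, r_h,
                                        loglik=-float(res.fun),
                                        converged=bool(res.success),
                                        at_boundary=bool(at_boundary))


def estimate_variance_components(records: pd.DataFrame, trait: str):
    """(sigma2_genetic, sigma2_nongenetic) REML estimates for one trait."""
    res = VarianceComponentModel(records, trait).fit()
    return res.sigma2_genetic, res.sigma2_nongenetic


def harmonic_mean_reps(records: pd.DataFrame, trait: str) -> float:
    """Harmonic mean of per-genotype replicate counts for one trait."""
    sub = _trait_records(validate_records(records), trait)
    counts = sub.groupby("genotype").size().to_numpy(float)
    return float(len(counts) / np.sum(1.0 / counts))


def reliability(sigma2_genetic: float, sigma2_nongenetic: float,
                r_harmonic: float) -> float:
    """Entry-mean reliability i2 = s2g / (s2g + s2e / r)."""
    if sigma2_genetic < 0 or sigma2_nongenetic < 0:
        raise ValueError("variance components must be non-negative")
    if r_harmonic < 1:
        raise ValueError("harmonic mean of replicates must be >= 1")
    if sigma2_genetic == 0 and sigma2_nongenetic == 0:
        raise ValueError("reliability undefined when both variances are zero")
    return sigma2_genetic / (sigma2_genetic + sigma2_nongenetic / r_harmonic)
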
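"""Association scans on training partitions.

Two engines are provided:

* :class:`MLMScan` — a single-locus kinship-adjusted mixed linear model.
  The polygenic/residual variance ratio is estimated once on the null
  model by eigen-REML and reused for every SNP (the P3D shortcut), so the
  per-SNP test is a weighted least-squares Wald t-test.
* :func:`multilocus_scan` — a forward-backward conditioned scan that adds
  the most significant SNP as a fixed covariate whenever it passes the
  Bonferroni threshold, re-tests the selected set jointly, and drops
  members that lose significance.  It plays the role multi-locus engines
  (FarmCPU/BLINK-style) play in GWAS-assisted prediction: producing a
  sparse detected-SNP set whose union/intersection feeds the prediction
  models.

Detected sets are thresholded at -log10(p) >= -log10(alpha / n_snps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix
from .mixedlm import eigen_reml

__all__ = [
    "GwasResult",
    "MLMScan",
    "mlm_scan",
    "multilocus_scan",
    "bonferroni_threshold",
    "select_fixed_snps",
    "pve",
]


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """-log10 Bonferroni significance threshold, -log10(alpha / n_snps)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_snps))


@dataclass
class GwasResult:
    """Per-SNP association statistics from one engine."""

    engine: str
    table: pd.DataFrame        # snp, chrom, pos, beta, se, pvalue, neglog10p,
                               # sigma2_resid, monomorphic, detected, pve
    threshold: float           # -log10 scale
    detected: list = field(default_factory=list)

    def __post_init__(self):
        pv = self.table["pvalue"].to_numpy()
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if not set(self.detected) <= set(self.table["snp"]):
            raise ValueError("detected set must be a subset of scanned SNPs")

    @property
    def pve(self) -> dict:
        sub = self.table[self.table["snp"].isin(self.detected)]
        return dict(zip(sub["snp"], sub["pve"]))


def _codes_and_map(g):
    if isinstance(g, GenotypeMatrix):
        return g.codes, g.markers
    g = np.asarray(g, float)
    markers = pd.DataFrame(
        {"id": [f"M{j}" for j in range(g.shape[1])],
         "chrom": ["0"] * g.shape[1], "pos": np.arange(1, g.shape[1] + 1)}
    )
    return g, markers


def _wald_scan(yt, Wt, Gt, wts):
    """Vectorised per-SNP Wald t-tests after whitening by sqrt(wts).

    Returns beta, se, pvalue, sigma2_resid, with NaN/1.0 entries for
    columns that have no variance left after projecting out Wt.
    """
    n, p = Wt.shape
    sw = np.sqrt(wts)
    A = Wt * sw[:, None]
    b = yt * sw
    Q, _ = np.linalg.qr(A)
    bq = b - Q @ (Q.T @ b)
    Gs = Gt * sw[:, None]
    Gq = Gs - Q @ (Q.T @ Gs)
    xx = np.einsum("ij,ij->j", Gq, Gq)
    xy = Gq.T @ bq
    df = n - p - 1
    ok = xx > 1e-10 * max(1.0, float(np.median(xx[xx > 0])) if (xx > 0).any() else 1.0)
    beta = np.zeros_like(xx)
    beta[ok] = xy[ok] / xx[ok]
    rss = float(bq @ bq) - beta * xy
    s2 = np.where(ok, np.maximum(rss, 0.0) / max(df, 1), np.nan)
    se = np.full_like(xx, np.nan)
    se[ok] = np.sqrt(s2[ok] / xx[ok])
    tstat = np.zeros_like(xx)
    nz = ok & (se > 0)
    tstat[nz] = beta[nz] / se[nz]
    pval = np.ones_like(xx)
    pval[nz] = 2.0 * stats.t.sf(np.abs(tstat[nz]), df)
    return beta, se, pval, s2, ~ok


def _result_table(markers, beta, se, pval, s2, flagged, codes, threshold, engine):
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.clip(pval, 1e-300, None))
    var_x = codes.var(axis=0, ddof=1) if codes.shape[0] > 1 else np.zeros(codes.shape[1])
    var_b = beta ** 2 * var_x
    with np.errstate(invalid="ignore"):
        pve_col = np.where(flagged | ~np.isfinite(s2), 0.0,
                           var_b / (var_b + np.where(np.isfinite(s2), s2, 1.0)))
    detected_mask = nlp >= threshold
    table = pd.DataFrame(
        {
            "snp": markers["id"].to_numpy(),
            "chrom": markers["chrom"].to_numpy(),
            "pos": markers["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "neglog10p": nlp,
            "sigma2_resid": s2,
            "monomorphic": flagged,
            "detected": detected_mask,
            "pve": pve_col,
        }
    )
    detected = table.loc[detected_mask].sort_values(["chrom", "pos"])["snp"].tolist()
    return GwasResult(engine, table, threshold, detected)


class MLMScan:
    """Single-locus mixed-linear-model scan with P3D variance components.

    Parameters
    ----------
    g : GenotypeMatrix or array of codes, lines x SNPs.
    y : adjusted phenotypes (BLUEs), aligned with the lines of `g`.
    K : KinshipMatrix or array; ``None`` collapses the model to per-SNP
        ordinary least squares.
    covariates : optional lines x k matrix (e.g. PCA coordinates).
    """

    def __init__(self, g, y, K=None, covariates=None):
        self.codes, self.markers = _codes_and_map(g)
        self.y = np.asarray(y, float)
        if self.y.shape[0] != self.codes.shape[0]:
            raise ValueError("y not aligned with genotype lines")
        if isinstance(K, KinshipMatrix):
            K = K.values
        self.K = None if K is None else np.asarray(K, float)
        self.covariates = (None if covariates is None
                           else np.atleast_2d(np.asarray(covariates, float)))

    def fit(self, alpha: float = 0.05) -> GwasResult:
        n, m = self.codes.shape
        W = np.ones((n, 1))
        if self.covariates is not None:
            C = self.covariates
            if C.shape[0] != n:
                C = C.T
            W = np.hstack([W, C])
        null = eigen_reml(self.y, W, K=self.K)
        wts = 1.0 / (null.d + null.lam)
        yt = null.U.T @ self.y
        Wt = null.U.T @ W
        Gt = null.U.T @ self.codes
        beta, se, pval, s2, flagged = _wald_scan(yt, Wt, Gt, wts)
        # the whitened-scale residual variance back on the data scale
        # (total non-marker variance: polygenic + iid residual)
        s2 = s2 * float(np.mean(null.d + null.lam))
        mono = self.codes.var(axis=0) <= 0
        flagged = flagged | mono
        pval = np.where(mono, 1.0, pval)
        beta = np.where(mono, 0.0, beta)
        thr = bonferroni_threshold(m, alpha)
        return _result_table(self.markers, beta, se, pval, s2, flagged,
                             self.codes, thr, engine="mlm")


def mlm_scan(g, y, K=None, covariates=None, alpha: float = 0.05) -> GwasResult:
    return MLMScan(g, y, K=K, covariates=covariates).fit(alpha=alpha)


def multilocus_scan(g, y, covariates=None, alpha: float = 0.05,
                    max_iter: int = 100) -> GwasResult:
    """Forward-backward Bonferroni-gated multi-locus scan.

    Iteratively conditions the genome scan on the currently selected SNPs
    (as fixed covariates), adds the most significant passing SNP
    (ties broken by (p, chrom, pos)), then re-tests the selected set
    jointly, dropping members that fall below the threshold.  Terminates
    when the set stabilises, or with a warning on cycle detection.
    """
    codes, markers = _codes_and_map(g)
    y = np.asarray(y, float)
    n, m = codes.shape
    thr = bonferroni_threshold(m, alpha)
    base = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        base = np.hstack([base, C])
    chroms = markers["chrom"].astype(str).to_numpy()
    poss = markers["pos"].to_numpy()
    ones = np.ones(n)

    def scan(selected):
        W = np.hstack([base, codes[:, selected]]) if selected else base
        return _wald_scan(y, W, codes, ones)

    def joint_pvalues(selected):
        """Marginal t-tests of each selected SNP in the joint model."""
        out = {}
        for j in selected:
            others = [k for k in selected if k != j]
            W = np.hstack([base, codes[:, others]]) if others else base
            _, _, pv, _, _ = _wald_scan(y, W, codes[:, [j]], ones)
            out[j] = pv[0]
        return out

    selected: list = []
    visited = set()
    for _ in range(max_iter):
        state = frozenset(selected)
        if state in visited:
            warnings.warn("multilocus scan revisited a SNP set; terminating")
            break
        visited.add(state)
        beta, se, pval, s2, flagged = scan(selected)
        cand = np.array([j for j in range(m) if j not in selected])
        changed = False
        if cand.size:
            order = sorted(cand, key=lambda j: (pval[j], chroms[j], poss[j]))
            best = order[0]
            if -np.log10(max(pval[best], 1e-300)) >= thr:
                selected.append(best)
                changed = True
        # backward: drop the weakest non-significant member, one at a time
        while selected:
            jp = joint_pvalues(selected)
            worst = max(selected, key=lambda j: (jp[j], chroms[j], poss[j]))
            if -np.log10(max(jp[worst], 1e-300)) < thr:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    # final reporting scan: each non-selected SNP conditioned on the set,
    # each selected SNP tested jointly against the others
    beta, se, pval, s2, flagged = scan(selected)
    if selected:
        jp = joint_pvalues(selected)
        for j in selected:
            W = np.hstack([base, codes[:, [k for k in selected if k != j]]]) \
                if len(selected) > 1 else base
            b_j, se_j, pv_j, s2_j, fl_j = _wald_scan(y, W, codes[:, [j]], ones)
            beta[j], se[j], pval[j], s2[j], flagged[j] = (
                b_j[0], se_j[0], pv_j[0], s2_j[0], fl_j[0]
            )
    mono = codes.var(axis=0) <= 0
    flagged = flagged | mono
    pval = np.where(mono, 1.0, pval)
    res = _result_table(markers, beta, se, pval, s2, flagged, codes, thr,
                        engine="multilocus")
    # detection is membership in the stabilised set, not the marginal test
    det_mask = np.zeros(m, dtype=bool)
    det_mask[selected] = True
    res.table["detected"] = det_mask
    res.detected = (res.table.loc[det_mask]
                    .sort_values(["chrom", "pos"])["snp"].tolist())
    return res


def select_fixed_snps(results: list, mode: str = "whole") -> list:
    """Combine detected sets across engines.

    mode "whole" is the union, "shared" the intersection; output is
    ordered by (chrom, pos).
    """
    if not results:
        raise ValueError("need at least one GwasResult")
    if mode not in ("whole", "shared"):
        raise ValueError(f"unknown mode {mode!r}")
    sets = [set(r.detected) for r in results]
    combined = set.union(*sets) if mode == "whole" else set.intersection(*sets)
    lookup = {}
    for r in results:
        for _, row in r.table.iterrows():
            lookup.setdefault(row["snp"], (str(row["chrom"]), int(row["pos"])))
    return sorted(combined, key=lambda s: lookup.get(s, ("", 0)))


def pve(g, y, snp_id: str, fitted_scan: GwasResult) -> float:
    """Proportion of phenotypic variance explained by one detected SNP:
    Var(x beta) / (Var(x beta) + sigma2_resid)."""
    codes, markers = _codes_and_map(g)
    ids = markers["id"].tolist()
    if snp_id not in ids:
        raise ValueError(f"SNP {snp_id} not in genotype matrix")
    row = fitted_scan.table[fitted_scan.table["snp"] == snp_id]
    if row.empty:
        raise ValueError(f"SNP {snp_id} not present in the scan")
    row = row.iloc[0]
    x = codes[:, ids.index(snp_id)]
    if x.var() <= 0 or row["monomorphic"]:
        return 0.0
    var_b = float(row["beta"]) ** 2 * float(np.var(x, ddof=1))
    s2 = float(row["sigma2_resid"])
    if var_b == 0:
        return 0.0
    return var_b / (var_b + s2)
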
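"""Model evaluation: repeated k-fold cross-validation and test-set validation.

Predictive ability (PA) is the Pearson correlation between observed BLUE
values and predicted genotypic values of held-out lines.  For the
GWAS-assisted variants, the association engines run only on the training
folds of each split and their detected SNPs enter that split's model as
fixed effects — the detected-SNP log per split makes the no-leakage
property auditable.

Method names: ``st_rrblup``, ``st_bayesb``, ``st_gwas_rrblup``,
``mt_rrblup``, ``mt_bayesb``, ``mt_gwas_rrblup``, ``rf``, ``xgboost``.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, compute_kinship, pca_covariates
from .gp import (BayesBGP, MultiTraitGP, RidgeGP, TreeModelConfig,
                 fit_tree_model)
from .gwas import mlm_scan, multilocus_scan, select_fixed_snps

__all__ = [
    "EvalConfig",
    "CVResult",
    "ValidationResult",
    "predictive_ability",
    "run_cv",
    "relative_improvement",
    "summarize_methods",
    "add_column_stats",
    "lsd_compare",
    "validate_testset",
    "validation_table",
]

ST_METHODS = ("st_rrblup", "st_bayesb", "st_gwas_rrblup", "rf", "xgboost")
MT_METHODS = ("mt_rrblup", "mt_bayesb", "mt_gwas_rrblup")

PredictiveAbility = namedtuple("PredictiveAbility", ["r", "pvalue"])


@dataclass
class EvalConfig:
    """Knobs shared by CV and test-set validation."""

    n_pcs: int = 3
    gwas_mode: str = "whole"          # "whole" (union) or "shared" (intersection)
    gwas_alpha: float = 0.05
    bayesb_burn_in: int = 1000
    bayesb_iterations: int = 6000
    tree_config_rf: TreeModelConfig = field(
        default_factory=lambda: TreeModelConfig(model="rf"))
    tree_config_xgb: TreeModelConfig = field(
        default_factory=lambda: TreeModelConfig(model="xgboost"))


@dataclass
class CVResult:
    results: pd.DataFrame             # trait, method, repeat, fold, pa, pvalue
    fold_assignments: dict            # repeat -> Series(line -> fold)
    detected_log: list                # dicts with trait/method/repeat/fold/snps
    seed: int
    k: int
    repeats: int

    def pa_values(self, trait: str, method: str) -> np.ndarray:
        sub = self.results
        return sub[(sub["trait"] == trait) & (sub["method"] == method)]["pa"].to_numpy()


@dataclass
class ValidationResult:
    results: pd.DataFrame             # trait, method, pa, pvalue
    detected_log: list


def predictive_ability(observed, predicted) -> PredictiveAbility:
    """Pearson correlation between observed BLUEs and predicted genotypic
    values, with the two-sided t-test p-value (df = n - 2)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted are not aligned")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs for a predictive ability")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("predictive ability undefined for a constant vector")
    r, p = stats.pearsonr(observed, predicted)
    return PredictiveAbility(float(r), float(p))


def relative_improvement(pa_method: float, pa_baseline: float) -> float:
    """Percent improvement over the baseline, 100 (pa - base) / base."""
    if pa_baseline == 0:
        raise ValueError("baseline predictive ability must be non-zero")
    return 100.0 * (pa_method - pa_baseline) / pa_baseline


# ---------------------------------------------------------------------------
# model fitting per split


def _gwas_fixed_set(codes, markers, y, cfg: EvalConfig):
    """Run the engine battery on a training partition; detected-SNP ids."""
    gm = GenotypeMatrix([f"L{i}" for i in range(codes.shape[0])],
                        markers, codes)
    K = compute_kinship(gm)
    pcs = pca_covariates(gm, k=min(cfg.n_pcs, codes.shape[0] - 1))
    res = [
        mlm_scan(gm, y, K=K, covariates=pcs, alpha=cfg.gwas_alpha),
        multilocus_scan(gm, y, covariates=pcs, alpha=cfg.gwas_alpha),
    ]
    return select_fixed_snps(res, mode=cfg.gwas_mode)


def _split_design(codes, marker_ids, fixed_ids):
    """Partition marker columns into fixed (X) and random (Z) blocks."""
    fixed_pos = [marker_ids.index(s) for s in fixed_ids]
    mask = np.ones(codes.shape[1], dtype=bool)
    mask[fixed_pos] = False
    X = codes[:, fixed_pos] if fixed_pos else None
    return X, codes[:, mask], mask


def _fit_st(method, y_tr, Z_tr, Z_te, X_tr, X_te, cfg: EvalConfig, seed: int):
    if method in ("st_rrblup",):
        return RidgeGP(y_tr, Z_tr).fit().predict(Z_te)
    if method == "st_gwas_rrblup":
        return RidgeGP(y_tr, Z_tr, X_tr).fit().predict(Z_te, X_te)
    if method == "st_bayesb":
        fit = BayesBGP(y_tr, Z_tr, burn_in=cfg.bayesb_burn_in,
                       iterations=cfg.bayesb_iterations).fit(seed=seed)
        return fit.predict(Z_te)
    if method == "rf":
        tc = TreeModelConfig(**{**vars(cfg.tree_config_rf), "seed": seed})
        return fit_tree_model(y_tr, Z_tr, tc).predict(Z_te)
    if method == "xgboost":
        tc = TreeModelConfig(**{**vars(cfg.tree_config_xgb), "seed": seed})
        return fit_tree_model(y_tr, Z_tr, tc).predict(Z_te)
    raise ValueError(f"unknown single-trait method {method!r}")


def _fit_mt(method, Y_tr, Z_tr, Z_te, X_tr, X_te, cfg: EvalConfig, seed: int):
    base = "bayesb" if method == "mt_bayesb" else "rrblup"
    kwargs = {}
    if base == "bayesb":
        kwargs = {"burn_in": cfg.bayesb_burn_in,
                  "iterations": cfg.bayesb_iterations}
    X = X_tr if method == "mt_gwas_rrblup" else None
    fit = MultiTraitGP(Y_tr, Z_tr, X, base=base, **kwargs).fit(seed=seed)
    return fit.predict(Z_te, X_te if method == "mt_gwas_rrblup" else None)


# ---------------------------------------------------------------------------
# cross-validation


def run_cv(geno: GenotypeMatrix, blues: pd.DataFrame, methods,
           k: int = 5, repeats: int = 5, seed: int = 0,
           config: EvalConfig | None = None) -> CVResult:
    """Repeated k-fold cross-validation of genomic prediction methods.

    `blues` is a genotype x trait table aligned to `geno.line_ids` (NaN
    where a trait was not observed).  Lines are shuffled once per repeat
    across the whole training set; single-trait methods use each trait's
    observed lines, multi-trait methods the complete cases.
    """
    cfg = config or EvalConfig()
    methods = list(methods)
    for mname in methods:
        if mname not in ST_METHODS + MT_METHODS:
            raise ValueError(f"unknown method {mname!r}")
    blues = blues.reindex(geno.line_ids)
    traits = list(blues.columns)
    codes = geno.codes
    marker_ids = geno.markers["id"].tolist()
    rng = np.random.default_rng(seed)
    rows, det_log, fold_assignments = [], [], {}
    n = geno.n_lines

    for rep in range(repeats):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % k
        fold_assignments[rep] = pd.Series(fold_of, index=geno.line_ids)
        for fold in range(k):
            te_mask = fold_of == fold
            # ---- single trait ----
            for trait in traits:
                obs = blues[trait].notna().to_numpy()
                tr_idx = np.flatnonzero(obs & ~te_mask)
                te_idx = np.flatnonzero(obs & te_mask)
                if len(te_idx) < 3 or len(tr_idx) < 3:
                    raise ValueError("fold with fewer than 3 lines")
                y_tr = blues[trait].to_numpy()[tr_idx]
                y_te = blues[trait].to_numpy()[te_idx]
                for mname in methods:
                    if mname not in ST_METHODS:
                        continue
                    sub_seed = (seed * 1000 + rep * 10 + fold) % (2 ** 31 - 1)
                    if mname == "st_gwas_rrblup":
                        fixed = _gwas_fixed_set(codes[tr_idx],
                                                geno.markers, y_tr, cfg)
                        det_log.append({"trait": trait, "method": mname,
                                        "repeat": rep, "fold": fold,
                                        "snps": list(fixed)})
                        X_tr, Z_tr, mask = _split_design(codes[tr_idx],
                                                         marker_ids, fixed)
                        X_te = codes[np.ix_(te_idx, [marker_ids.index(s) for s in fixed])] \
                            if fixed else None
                        pred = _fit_st(mname, y_tr, Z_tr, codes[te_idx][:, mask],
                                       X_tr, X_te, cfg, sub_seed)
                    else:
                        pred = _fit_st(mname, y_tr, codes[tr_idx], codes[te_idx],
                                       None, None, cfg, sub_seed)
                    pa = predictive_ability(y_te, pred)
                    rows.append((trait, mname, rep, fold, pa.r, pa.pvalue))
            # ---- multi trait ----
            mt_requested = [mname for mname in methods if mname in MT_METHODS]
            if mt_requested:
                complete = blues.notna().all(axis=1).to_numpy()
                tr_idx = np.flatnonzero(complete & ~te_mask)
                te_idx = np.flatnonzero(complete & te_mask)
                if len(te_idx) < 3 or len(tr_idx) < 3:
                    raise ValueError("fold with fewer than 3 complete-case lines")
                Y_tr = blues.iloc[tr_idx]
                Y_te = blues.iloc[te_idx]
                fixed_mt = None
                for mname in mt_requested:
                    sub_seed = (seed * 1000 + rep * 10 + fold) % (2 ** 31 - 1)
                    if mname == "mt_gwas_rrblup":
                        if fixed_mt is None:
                            per_trait = []
                            for trait in traits:
                                per_trait.extend(_gwas_fixed_set(
                                    codes[tr_idx], geno.markers,
                                    Y_tr[trait].to_numpy(), cfg))
                            fixed_mt = sorted(set(per_trait),
                                              key=lambda s: marker_ids.index(s))
                        det_log.append({"trait": "ALL", "method": mname,
                                        "repeat": rep, "fold": fold,
                                        "snps": list(fixed_mt)})
                        X_tr, Z_tr, mask = _split_design(codes[tr_idx],
                                                         marker_ids, fixed_mt)
                        X_te = codes[np.ix_(te_idx, [marker_ids.index(s) for s in fixed_mt])] \
                            if fixed_mt else None
                        pred = _fit_mt(mname, Y_tr, Z_tr, codes[te_idx][:, mask],
                                       X_tr, X_te, cfg, sub_seed)
                    else:
                        pred = _fit_mt(mname, Y_tr, codes[tr_idx], codes[te_idx],
                                       None, None, cfg, sub_seed)
                    for trait in traits:
                        pa = predictive_ability(Y_te[trait].to_numpy(),
                                                pred[trait].to_numpy())
                        rows.append((trait, mname, rep, fold, pa.r, pa.pvalue))

    results = pd.DataFrame(
        rows, columns=["trait", "method", "repeat", "fold", "pa", "pvalue"])
    return CVResult(results, fold_assignments, det_log, seed, k, repeats)


# ---------------------------------------------------------------------------
# summaries and comparisons


def summarize_methods(cv: CVResult) -> pd.DataFrame:
    """Method x trait table of mean PA over all folds, plus per-trait
    column average and sample standard deviation over the method means."""
    means = (cv.results.groupby(["method", "trait"])["pa"].mean()
             .unstack("trait"))
    return add_column_stats(means)


def add_column_stats(means: pd.DataFrame) -> pd.DataFrame:
    """Append 'Average' and 'SD' rows (sample SD, n-1) to a method-mean
    table — the bottom rows of a CV report."""
    out = means.copy()
    out.loc["Average"] = means.mean(axis=0)
    out.loc["SD"] = means.std(axis=0, ddof=1)
    return out


def lsd_compare(cv: CVResult, trait: str, alpha: float = 0.05,
                methods=None, restrict_folds=None) -> dict:
    """Fisher's LSD compact-letter groups of methods for one trait.

    One-way ANOVA on the per-fold PA values (method as factor), pairwise
    LSD = t(alpha/2, df_error) sqrt(2 MSE / n); methods sharing a letter
    are not significantly different.  `restrict_folds` optionally limits
    the comparison to a set of (repeat, fold) splits (e.g. those where all
    engines detected shared SNPs).
    """
    sub = cv.results[cv.results["trait"] == trait]
    if methods is not None:
        sub = sub[sub["method"].isin(methods)]
    if restrict_folds is not None:
        keep = sub.apply(lambda r: (r["repeat"], r["fold"]) in set(restrict_folds),
                         axis=1)
        sub = sub[keep]
    groups = {mname: g["pa"].to_numpy() for mname, g in sub.groupby("method")}
    if not groups:
        raise ValueError(f"no PA values for trait {trait!r}")
    if len(groups) == 1:
        return {next(iter(groups)): "a"}
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("LSD test requires equal replication per method")
    n_rep = sizes.pop()
    t_methods = sorted(groups, key=lambda mname: -groups[mname].mean())
    means = np.array([groups[mname].mean() for mname in t_methods])
    all_vals = np.concatenate([groups[mname] for mname in t_methods])
    grand = all_vals.mean()
    sse = sum(((groups[mname] - groups[mname].mean()) ** 2).sum()
              for mname in t_methods)
    df_err = len(all_vals) - len(t_methods)
    mse = sse / df_err
    lsd = stats.t.ppf(1 - alpha / 2, df_err) * np.sqrt(2 * mse / n_rep)
    # compact letter display by interval sweep over descending means
    runs = []
    for i in range(len(t_methods)):
        j = i
        while j + 1 < len(t_methods) and means[i] - means[j + 1] <= lsd:
            j += 1
        if not runs or runs[-1][1] < j:
            runs.append((i, j))
    letters = {mname: "" for mname in t_methods}
    for rix, (i, j) in enumerate(runs):
        ch = chr(ord("a") + rix)
        for idx in range(i, j + 1):
            letters[t_methods[idx]] += ch
    return letters


# ---------------------------------------------------------------------------
# independent test-set validation


def validate_testset(train_geno: GenotypeMatrix, train_blues: pd.DataFrame,
                     test_geno: GenotypeMatrix, test_blues: pd.DataFrame,
                     methods, seed: int = 0,
                     config: EvalConfig | None = None) -> ValidationResult:
    """Fit each method on the full training set and score it on an unseen
    test set (e.g. MAGIC DH lines); GWAS-assisted variants run their
    engines on the full training set."""
    cfg = config or EvalConfig()
    overlap = set(train_geno.line_ids) & set(test_geno.line_ids)
    if overlap:
        raise ValueError(f"train/test line overlap: {sorted(overlap)[:5]}")
    if train_geno.markers["id"].tolist() != test_geno.markers["id"].tolist():
        raise ValueError("train and test sets must share the marker panel")
    train_blues = train_blues.reindex(train_geno.line_ids)
    test_blues = test_blues.reindex(test_geno.line_ids)
    traits = list(train_blues.columns)
    marker_ids = train_geno.markers["id"].tolist()
    rows, det_log = [], []

    for mname in methods:
        if mname in ST_METHODS:
            for trait in traits:
                obs = train_blues[trait].notna().to_numpy()
                y_tr = train_blues[trait].to_numpy()[obs]
                Ztr_full = train_geno.codes[obs]
                if mname == "st_gwas_rrblup":
                    fixed = _gwas_fixed_set(Ztr_full, train_geno.markers, y_tr, cfg)
                    det_log.append({"trait": trait, "method": mname,
                                    "snps": list(fixed)})
                    X_tr, Z_tr, mask = _split_design(Ztr_full, marker_ids, fixed)
                    X_te = test_geno.codes[:, [marker_ids.index(s) for s in fixed]] \
                        if fixed else None
                    pred = _fit_st(mname, y_tr, Z_tr, test_geno.codes[:, mask],
                                   X_tr, X_te, cfg, seed)
                else:
                    pred = _fit_st(mname, y_tr, Ztr_full, test_geno.codes,
                                   None, None, cfg, seed)
                ok = test_blues[trait].notna().to_numpy()
                pa = predictive_ability(test_blues[trait].to_numpy()[ok],
                                        np.asarray(pred)[ok])
                rows.append((trait, mname, pa.r, pa.pvalue))
        elif mname in MT_METHODS:
            complete = train_blues.notna().all(axis=1).to_numpy()
            Y_tr = train_blues[complete]
            Ztr_full = train_geno.codes[complete]
            if mname == "mt_gwas_rrblup":
                per_trait = []
                for trait in traits:
                    per_trait.extend(_gwas_fixed_set(
                        Ztr_full, train_geno.markers,
                        Y_tr[trait].to_numpy(), cfg))
                fixed = sorted(set(per_trait), key=lambda s: marker_ids.index(s))
                det_log.append({"trait": "ALL", "method": mname,
                                "snps": list(fixed)})
                X_tr, Z_tr, mask = _split_design(Ztr_full, marker_ids, fixed)
                X_te = test_geno.codes[:, [marker_ids.index(s) for s in fixed]] \
                    if fixed else None
                pred = _fit_mt(mname, Y_tr, Z_tr, test_geno.codes[:, mask],
                               X_tr, X_te, cfg, seed)
            else:
                pred = _fit_mt(mname, Y_tr, Ztr_full, test_geno.codes,
                               None, None, cfg, seed)
            for trait in traits:
                ok = test_blues[trait].notna().to_numpy()
                pa = predictive_ability(test_blues[trait].to_numpy()[ok],
                                        pred[trait].to_numpy()[ok])
                rows.append((trait, mname, pa.r, pa.pvalue))
        else:
            raise ValueError(f"unknown method {mname!r}")

    results = pd.DataFrame(rows, columns=["trait", "method", "pa", "pvalue"])
    return ValidationResult(results, det_log)


def validation_table(vr: ValidationResult) -> pd.DataFrame:
    """Trait x method PA table with per-method averages over traits and
    MT/ST grand averages (test-set report layout)."""
    table = vr.results.pivot(index="trait", columns="method", values="pa")
    avg = table.mean(axis=0)
    table.loc["Average"] = avg
    mt = [c for c in table.columns if c.startswith("mt_")]
    st = [c for c in table.columns if not c.startswith("mt_")]
    grand = {}
    if mt:
        grand["MT"] = float(avg[mt].mean())
    if st:
        grand["ST"] = float(avg[st].mean())
    table.attrs["grand_averages"] = grand
    return table
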
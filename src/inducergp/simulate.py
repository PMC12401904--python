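"""Synthetic multi-family doubled-haploid (DH) populations.

Emulates the structure of a maize haploid-inducer breeding study: a small
panel of fully homozygous founders, ~23 biparental DH families derived from
them, an 8-way MAGIC DH test set, and four traits with mixed genetic
architectures (one oligogenic trait with a few major QTL, the rest
polygenic) measured in an unbalanced two-year, two-block field design.

Meiosis uses a Haldane (no-interference) model: crossover counts are
Poisson with mean ``chrom_length_cM / 100`` per chromosome and crossover
positions are uniform on the genetic map.  A DH line is a single
recombinant gamete doubled to homozygosity, so every simulated genotype is
coded in {-1, 1} before any missingness is injected.

Trait correlations are induced by Cholesky-mixing the standardized
minor-polygenic scores across traits; the minor-component correlation is
inflated by ``1/sqrt((1-f_i)(1-f_j))`` (f = major-QTL fraction of genetic
variance) so that the *total* genetic correlation matches the target even
though trait-specific major QTL are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "TraitArch",
    "SimConfig",
    "TruthTable",
    "Study",
    "simulate_founders",
    "simulate_dh_family",
    "simulate_magic",
    "simulate_phenotypes",
    "inject_missing_genotypes",
    "simulate_study",
    "default_config",
]


@dataclass
class TraitArch:
    """Genetic architecture of one trait.

    major_effect_fraction is the share of genetic variance carried by the
    major QTL; h2_plot is the plot-level heritability
    sigma2_g / (sigma2_g + sigma2_e); genetic_var and mean set the scale of
    the trait (units of the trait, squared for the variance).
    genetic_corr is this trait's row of the trait-trait genetic correlation
    matrix.
    """

    name: str
    n_major_qtl: int = 0
    n_minor_qtl: int = 300
    major_effect_fraction: float = 0.0
    h2_plot: float = 0.6
    genetic_var: float = 1.0
    mean: float = 0.0
    genetic_corr: tuple = ()

    def __post_init__(self):
        if not 0 < self.h2_plot < 1:
            if self.h2_plot == 1.0:  # noiseless limit allowed for testing
                pass
            else:
                raise ValueError(f"h2_plot must be in (0, 1], got {self.h2_plot}")
        if not 0 <= self.major_effect_fraction <= 1:
            raise ValueError("major_effect_fraction must be in [0, 1]")
        if self.n_major_qtl == 0 and self.major_effect_fraction > 0:
            raise ValueError("major_effect_fraction > 0 requires major QTL")
        if self.n_major_qtl < 0 or self.n_minor_qtl < 0:
            raise ValueError("QTL counts must be non-negative")
        if self.genetic_var <= 0:
            raise ValueError("genetic_var must be positive")

    @property
    def residual_var(self) -> float:
        if self.h2_plot >= 1.0:
            return 0.0
        return self.genetic_var * (1.0 - self.h2_plot) / self.h2_plot


@dataclass
class SimConfig:
    """Study-level simulation settings."""

    n_founders: int = 9
    n_chrom: int = 10
    snps_per_chrom: int = 700
    chrom_length_cM: float = 150.0
    families: list = field(default_factory=list)  # (parentA, parentB, n_DH)
    magic_n_lines: int = 11
    traits: list = field(default_factory=list)
    years: int = 2
    blocks_per_year: int = 2
    missing_pheno_rate: float = 0.3
    missing_geno_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_chrom", "snps_per_chrom", "magic_n_lines",
                     "years", "blocks_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.missing_pheno_rate < 1:
            raise ValueError("missing_pheno_rate must be in [0, 1)")
        if not 0 <= self.missing_geno_rate < 1:
            raise ValueError("missing_geno_rate must be in [0, 1)")
        for a, b, n in self.families:
            if not (0 <= a < self.n_founders and 0 <= b < self.n_founders):
                raise ValueError(f"family ({a}, {b}) references invalid founders")
            if n <= 0:
                raise ValueError("family sizes must be positive")
        if self.traits:
            corr_from_traits(self.traits)

    def corr_matrix(self) -> np.ndarray:
        return corr_from_traits(self.traits)


def corr_from_traits(traits: list) -> np.ndarray:
    """Assemble and validate the trait-trait genetic correlation matrix
    from the per-trait rows."""
    t = len(traits)
    R = np.eye(t)
    for i, tr in enumerate(traits):
        row = tr.genetic_corr
        if row is None or len(row) == 0:
            continue
        if len(row) != t:
            raise ValueError(f"genetic_corr row of {tr.name} has wrong length")
        R[i] = row
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("genetic correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("genetic correlation matrix needs unit diagonal")
    if t > 1 and np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("genetic correlation matrix must be PSD")
    return R


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated phenotypes."""

    genetic_values: pd.DataFrame       # lines x traits, true genotypic values
    qtl: pd.DataFrame                  # trait, marker id, index, class, effect
    effects: pd.DataFrame              # markers x traits effective additive effects
    realized_corr: pd.DataFrame        # realized genetic correlation of true values
    residual_sd: dict
    year_effects: pd.DataFrame
    block_effects: pd.DataFrame


# ---------------------------------------------------------------------------
# founders and meiosis


def simulate_founders(config: SimConfig) -> GenotypeMatrix:
    """Fully homozygous founder panel with a random genetic map.

    Per-SNP founder allele frequencies are drawn from U(0.25, 0.75) so that
    at least ~95% of SNPs segregate among the founders.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config.snps_per_chrom <= 0 or config.n_chrom <= 0:
        raise ValueError("need at least one SNP on at least one chromosome")
    rng = np.random.default_rng(config.seed)
    letters = np.array(list("ACGT"))
    meta = []
    for c in range(1, config.n_chrom + 1):
        cm = np.sort(rng.uniform(0.0, config.chrom_length_cM, config.snps_per_chrom))
        bp = np.floor(cm * 1e6).astype(np.int64) + 1
        for i in range(1, len(bp)):          # strictly increasing positions
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        for pos, cmx in zip(bp, cm):
            pair = rng.choice(4, size=2, replace=False)
            meta.append(
                {
                    "id": f"S{c}_{pos}",
                    "chrom": str(c),
                    "pos": int(pos),
                    "cm": float(cmx),
                    "allele_major": letters[pair[0]],
                    "allele_minor": letters[pair[1]],
                }
            )
    markers = pd.DataFrame(meta)
    m = len(markers)
    p = rng.uniform(0.25, 0.75, size=m)
    codes = np.where(rng.random((config.n_founders, m)) < p, 1.0, -1.0)
    ids = [f"F{i + 1}" for i in range(config.n_founders)]
    return GenotypeMatrix(ids, markers, codes)


def _chrom_slices(markers: pd.DataFrame):
    slices = []
    chroms = markers["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            slices.append(slice(start, i))
            start = i
    return slices


def _recomb_choice(cm: np.ndarray, length: float, rng) -> np.ndarray:
    """Boolean mask: True where the gamete copies haplotype A."""
    n_x = rng.poisson(length / 100.0)
    xpos = np.sort(rng.uniform(0.0, length, size=n_x))
    seg = np.searchsorted(xpos, cm)
    start = rng.integers(2)
    return (seg + start) % 2 == 0


def _gamete(hapA, hapB, cm, length, rng):
    """One recombinant gamete; hapA/hapB are tuples of parallel arrays."""
    mask = _recomb_choice(cm, length, rng)
    return tuple(np.where(mask, a, b) for a, b in zip(hapA, hapB))


def simulate_dh_family(parentA: np.ndarray, parentB: np.ndarray, n_DH: int,
                       markers: pd.DataFrame, seed: int,
                       prefix: str = "DH") -> GenotypeMatrix:
    """DH progeny of a biparental cross.

    Each line is a single recombinant F1 gamete doubled to homozygosity.
    Crossovers follow a Poisson process on the cM map (Haldane model).
    """
    parentA = np.asarray(parentA, dtype=float)
    parentB = np.asarray(parentB, dtype=float)
    for p in (parentA, parentB):
        if not np.isin(p, (-1.0, 1.0)).all():
            raise ValueError("parents must be fully homozygous ({-1, 1} codes)")
    if n_DH <= 0:
        raise ValueError("n_DH must be positive")
    rng = np.random.default_rng(seed)
    slices = _chrom_slices(markers)
    cm_all = markers["cm"].to_numpy()
    codes = np.empty((n_DH, len(markers)))
    for i in range(n_DH):
        for sl in slices:
            cm = cm_all[sl]
            length = float(cm.max()) if len(cm) else 0.0
            (codes[i, sl],) = _gamete((parentA[sl],), (parentB[sl],), cm, length, rng)
    ids = [f"{prefix}_{i + 1:03d}" for i in range(n_DH)]
    return GenotypeMatrix(ids, markers.copy(), codes)


def simulate_magic(founders: GenotypeMatrix, n_lines: int, seed: int,
                   track_ancestry: bool = False):
    """Multi-parent (8-way funnel) MAGIC DH lines.

    The funnel order is randomized per line; founder panels smaller than 8
    are recycled to fill the funnel slots.  With ``track_ancestry`` the
    per-locus founder-of-origin is returned alongside the genotypes.
    """
    nf = founders.n_lines
    if nf < 2:
        raise ValueError("MAGIC requires at least 2 founders")
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    rng = np.random.default_rng(seed)
    slices = _chrom_slices(founders.markers)
    cm_all = founders.markers["cm"].to_numpy()
    m = founders.n_markers
    codes = np.empty((n_lines, m))
    ancestry = np.empty((n_lines, m), dtype=np.int64)
    for i in range(n_lines):
        order = rng.permutation(nf)
        funnel = [int(order[k % nf]) for k in range(8)]
        for sl in slices:
            cm = cm_all[sl]
            length = float(cm.max()) if len(cm) else 0.0
            haps = [
                (founders.codes[f, sl], np.full(sl.stop - sl.start, f))
                for f in funnel
            ]
            # F1s -> 4-ways -> 8-way -> DH gamete
            f1 = [(haps[2 * k], haps[2 * k + 1]) for k in range(4)]
            four = []
            for k in range(2):
                g1 = _gamete(*f1[2 * k], cm, length, rng)
                g2 = _gamete(*f1[2 * k + 1], cm, length, rng)
                four.append((g1, g2))
            g8a = _gamete(*four[0], cm, length, rng)
            g8b = _gamete(*four[1], cm, length, rng)
            dh = _gamete(g8a, g8b, cm, length, rng)
            codes[i, sl], ancestry[i, sl] = dh
    ids = [f"MAGIC_{i + 1:03d}" for i in range(n_lines)]
    g = GenotypeMatrix(ids, founders.markers.copy(), codes)
    if track_ancestry:
        return g, ancestry
    return g


def inject_missing_genotypes(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a uniform random fraction of calls to missing (for imputer tests)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = g.codes.copy()
    codes[rng.random(codes.shape) < rate] = np.nan
    return GenotypeMatrix(list(g.line_ids), g.markers.copy(), codes)


# ---------------------------------------------------------------------------
# phenotypes


def _standardize(x: np.ndarray):
    mu = x.mean()
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate (zero-variance) genetic component; "
                         "increase QTL numbers or population size")
    return (x - mu) / sd, mu, sd


def simulate_phenotypes(genos: GenotypeMatrix, traits: list, design: SimConfig,
                        seed: int):
    """Plot-level phenotype records plus ground truth.

    The generative model mirrors the downstream analysis model: fixed year
    and block-in-year shifts, a genotypic value built from major QTL and a
    correlated minor-polygenic component, and iid Gaussian plot residuals
    scaled so the plot-level heritability matches each trait's target.
    Records are then thinned at random by ``design.missing_pheno_rate``.
    """
    for tr in traits:
        if not 0 < tr.h2_plot <= 1:
            raise ValueError(f"h2_plot for {tr.name} outside (0, 1]")
    rng = np.random.default_rng(seed)
    Z = genos.codes
    if np.isnan(Z).any():
        raise ValueError("phenotype simulation needs complete genotypes")
    n, m = Z.shape
    t = len(traits)
    freqs = genos.major_allele_freq()
    segregating = np.flatnonzero((freqs > 0) & (freqs < 1))
    if segregating.size == 0:
        raise ValueError("no segregating markers")

    R = corr_from_traits(traits) if t > 1 else np.ones((1, 1))
    f = np.array([tr.major_effect_fraction for tr in traits])
    # inflate the minor-component correlation so the total hits the target
    Rmin = R.copy()
    for i in range(t):
        for j in range(t):
            if i != j:
                denom = np.sqrt((1 - f[i]) * (1 - f[j]))
                if denom == 0:
                    if R[i, j] != 0:
                        raise ValueError("nonzero correlation target with fully "
                                         "major-QTL traits is infeasible")
                    Rmin[i, j] = 0.0
                else:
                    Rmin[i, j] = R[i, j] / denom
    if np.linalg.eigvalsh(Rmin).min() < -1e-8:
        raise ValueError("correlation targets infeasible given major-QTL fractions")

    qtl_rows = []
    major_std = np.zeros((n, t))
    major_alpha = np.zeros((m, t))    # per-trait major effects on the Z scale
    minor_raw = np.zeros((n, t))
    minor_alpha = np.zeros((m, t))
    used = set()
    for k, tr in enumerate(traits):
        avail = np.array([s for s in segregating if s not in used])
        pick = rng.choice(avail, size=tr.n_major_qtl + tr.n_minor_qtl, replace=False)
        used.update(int(x) for x in pick[: tr.n_major_qtl])  # majors unique per trait
        maj, mino = pick[: tr.n_major_qtl], pick[tr.n_major_qtl:]
        if tr.n_major_qtl:
            beta = rng.normal(size=tr.n_major_qtl)
            score = Z[:, maj] @ beta
            std, mu, sd = _standardize(score)
            major_std[:, k] = std
            major_alpha[maj, k] = beta / sd
            for jj, b in zip(maj, beta):
                qtl_rows.append({"trait": tr.name, "marker": genos.markers["id"].iloc[int(jj)],
                                 "index": int(jj), "class": "major", "effect": float(b / sd)})
        if tr.n_minor_qtl:
            beta = rng.normal(size=tr.n_minor_qtl)
            minor_raw[:, k] = Z[:, mino] @ beta
            minor_alpha[mino, k] = beta
            for jj, b in zip(mino, beta):
                qtl_rows.append({"trait": tr.name, "marker": genos.markers["id"].iloc[int(jj)],
                                 "index": int(jj), "class": "minor", "effect": float(b)})
        elif tr.n_major_qtl == 0:
            raise ValueError(f"trait {tr.name} has no QTL at all")

    # standardize, whiten (exact sample-correlation control), then mix
    has_minor = np.array([tr.n_minor_qtl > 0 for tr in traits])
    S = np.zeros((n, t))
    for k in range(t):
        if has_minor[k]:
            std, mu, sd = _standardize(minor_raw[:, k])
            S[:, k] = std
            minor_alpha[:, k] /= sd
    if t > 1 and has_minor.sum() > 1 and n > t:
        idx = np.flatnonzero(has_minor)
        C = np.corrcoef(S[:, idx], rowvar=False)
        Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(idx)))
        Lt = np.linalg.cholesky(Rmin[np.ix_(idx, idx)] + 1e-10 * np.eye(len(idx)))
        M = np.linalg.solve(Lc.T, Lt.T)      # S_w = S inv(Lc)', mixed = S_w Lt'
        S[:, idx] = S[:, idx] @ M
        Ascale = np.zeros((t, t))
        Ascale[np.ix_(idx, idx)] = M
    else:
        Ascale = np.diag(has_minor.astype(float))
    minor_alpha_mixed = minor_alpha @ Ascale

    # family structure and LD correlate any two marker scores through
    # relatedness, so each major score is residualized against the mixed
    # minor components (and restandardized) to keep the realized
    # between-trait correlation on target
    any_minor = has_minor.any()
    for k, tr in enumerate(traits):
        if tr.n_major_qtl and any_minor:
            coef, *_ = np.linalg.lstsq(S, major_std[:, k], rcond=None)
            resid = major_std[:, k] - S @ coef
            resid_std, _, sd_r = _standardize(resid)
            major_std[:, k] = resid_std
            major_alpha[:, k] = (major_alpha[:, k] - minor_alpha_mixed @ coef) / sd_r

    gvals = np.zeros((n, t))
    alpha = np.zeros((m, t))      # final effective additive effects
    for k, tr in enumerate(traits):
        scale = np.sqrt(tr.genetic_var)
        g = (np.sqrt(tr.major_effect_fraction) * major_std[:, k]
             + np.sqrt(1 - tr.major_effect_fraction) * S[:, k])
        gvals[:, k] = tr.mean + scale * g
        alpha[:, k] = scale * (
            np.sqrt(tr.major_effect_fraction) * major_alpha[:, k]
            + np.sqrt(1 - tr.major_effect_fraction) * minor_alpha_mixed[:, k]
        )

    realized = np.corrcoef(gvals, rowvar=False) if t > 1 else np.ones((1, 1))
    names = [tr.name for tr in traits]

    # field design: complete (year x block) factorial, then random thinning
    years = [f"Y{i + 1}" for i in range(design.years)]
    blocks = [f"B{j + 1}" for j in range(design.blocks_per_year)]
    resid_sd = {tr.name: np.sqrt(tr.residual_var) for tr in traits}
    year_eff = {tr.name: rng.normal(0.0, resid_sd[tr.name], size=len(years))
                for tr in traits}
    block_eff = {tr.name: rng.normal(0.0, 0.5 * resid_sd[tr.name],
                                     size=(len(years), len(blocks)))
                 for tr in traits}
    recs = []
    for k, tr in enumerate(traits):
        for yi, year in enumerate(years):
            for bj, block in enumerate(blocks):
                vals = (gvals[:, k] + year_eff[tr.name][yi]
                        + block_eff[tr.name][yi, bj]
                        + rng.normal(0.0, resid_sd[tr.name], size=n))
                for line, v in zip(genos.line_ids, vals):
                    recs.append((line, year, block, tr.name, float(v)))
    records = pd.DataFrame(recs, columns=["genotype", "year", "block", "trait", "value"])
    if design.missing_pheno_rate > 0:
        keep = rng.random(len(records)) >= design.missing_pheno_rate
        records = records[keep].reset_index(drop=True)

    truth = TruthTable(
        genetic_values=pd.DataFrame(gvals, index=list(genos.line_ids), columns=names),
        qtl=pd.DataFrame(qtl_rows),
        effects=pd.DataFrame(alpha, index=genos.markers["id"].tolist(), columns=names),
        realized_corr=pd.DataFrame(realized, index=names, columns=names),
        residual_sd=resid_sd,
        year_effects=pd.DataFrame(year_eff, index=years),
        block_effects=pd.DataFrame(
            {tr.name: block_eff[tr.name].ravel() for tr in traits},
            index=[f"{y}:{b}" for y in years for b in blocks],
        ),
    )
    return records, truth


# ---------------------------------------------------------------------------
# full-study orchestration


@dataclass
class Study:
    """A complete simulated training + MAGIC-test study."""

    founders: GenotypeMatrix
    train: GenotypeMatrix            # clean codes
    train_missing: GenotypeMatrix    # with injected missing genotype calls
    test: GenotypeMatrix             # MAGIC DH lines
    records: pd.DataFrame            # training plot records
    test_records: pd.DataFrame       # test-set plot records (final year only)
    truth: TruthTable


def default_families():
    """23 biparental families (founder index pairs and DH counts) mirroring
    a multi-family inducer panel: sizes 5-48, 334 lines in total."""
    sizes = [5, 48, 8, 12, 30, 10, 14, 22, 6, 18, 9, 25, 7, 16, 11, 28,
             13, 9, 15, 6, 8, 6, 8]
    pairs = []
    k = 0
    for i in range(9):
        for j in range(i + 1, 9):
            pairs.append((i, j))
    return [(pairs[k][0], pairs[k][1], n) for k, n in enumerate(sizes)]


def default_config(seed: int = 0) -> SimConfig:
    """Default study conditions: 9 founders, 23 DH families (334 lines),
    10 chromosomes x 700 SNPs, 11 MAGIC test lines, four traits with
    variance components of the magnitudes seen in inducer field trials and
    weak genetic correlations; one oligogenic trait (HIR) with 2 major plus
    50 minor QTL."""
    traits = [
        TraitArch("DTF", 0, 300, 0.0, h2_plot=5.27 / (5.27 + 1.78),
                  genetic_var=5.27, mean=75.0,
                  genetic_corr=(1.0, -0.228, 0.186, 0.0)),
        TraitArch("HIR", 2, 50, 0.5, h2_plot=12.18 / (12.18 + 7.25),
                  genetic_var=12.18, mean=10.0,
                  genetic_corr=(-0.228, 1.0, 0.0, 0.0)),
        TraitArch("PHT", 0, 300, 0.0, h2_plot=241.0 / (241.0 + 93.2),
                  genetic_var=241.0, mean=150.0,
                  genetic_corr=(0.186, 0.0, 1.0, 0.156)),
        TraitArch("PBL", 0, 300, 0.0, h2_plot=2379.0 / (2379.0 + 1661.0),
                  genetic_var=2379.0, mean=60.0,
                  genetic_corr=(0.0, 0.0, 0.156, 1.0)),
    ]
    return SimConfig(
        n_founders=9,
        n_chrom=10,
        snps_per_chrom=700,
        chrom_length_cM=150.0,
        families=default_families(),
        magic_n_lines=11,
        traits=traits,
        years=2,
        blocks_per_year=2,
        missing_pheno_rate=0.3,
        missing_geno_rate=0.02,
        seed=seed,
    )


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> Study:
    """Generate a full training + MAGIC-test study from one config."""
    if config is None:
        config = default_config(seed if seed is not None else 0)
    if seed is not None:
        config.seed = seed
    founders = simulate_founders(config)
    parts = []
    for fam_idx, (a, b, n) in enumerate(config.families, start=1):
        fam = simulate_dh_family(
            founders.codes[a], founders.codes[b], n, founders.markers,
            seed=config.seed * 100003 + fam_idx, prefix=f"FAM{fam_idx:02d}",
        )
        parts.append(fam)
    train_codes = np.vstack([p.codes for p in parts] + [founders.codes])
    train_ids = [i for p in parts for i in p.line_ids] + list(founders.line_ids)
    train = GenotypeMatrix(train_ids, founders.markers.copy(), train_codes)
    test = simulate_magic(founders.subset_lines(range(min(8, founders.n_lines))),
                          config.magic_n_lines, seed=config.seed * 100003 + 99)
    combined = GenotypeMatrix(
        train_ids + list(test.line_ids),
        founders.markers.copy(),
        np.vstack([train.codes, test.codes]),
    )
    records, truth = simulate_phenotypes(combined, config.traits, config,
                                         seed=config.seed * 100003 + 7)
    is_test = records["genotype"].isin(test.line_ids)
    last_year = f"Y{config.years}"
    test_records = records[is_test & (records["year"] == last_year)].reset_index(drop=True)
    records = records[~is_test].reset_index(drop=True)
    train_missing = inject_missing_genotypes(
        train, config.missing_geno_rate, seed=config.seed * 100003 + 13
    )
    return Study(founders, train, train_missing, test, records, test_records, truth)
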
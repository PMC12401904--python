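# Methods

This note documents the models, the simulator, the numerical choices, and
the limits of what the test suite demonstrates.

## Phenotype adjustment

Plot records `(genotype, year, block, trait, value)` are fitted by
ordinary least squares with treatment coding (one dropped level per
factor): intercept, year, block nested in year, genotype. The BLUE of a
genotype is its estimated marginal mean — the prediction averaged with
equal weights over all year and block-in-year levels. Aliased block cells
(empty design cells) are dropped with a warning; a genotype column aliased
with year/block is a confounded design and raises, naming the genotypes.
A year x genotype interaction term is available behind a flag for
sensitivity analysis but is off by default; the four traits are assumed to
share a common error variance across years.

Variance components come from the companion mixed model (year and
block-in-year fixed, genotype random, iid residual), fitted by REML
profiled over the genotype/residual variance ratio λ. Because the
genotype incidence matrix Z satisfies Z'Z = diag(n_g), the matrix
H = I + λZZ' inverts in O(n) by Woodbury and log|H| = Σ log(1 + λ n_g),
so each profile evaluation is linear in the number of records. The 1-D
profile is minimized by bounded Brent search on log10 λ over [-10, 10]
(ratio tolerance 1e-8); a boundary solution is reported as σ²_g = 0 with a
flag. On balanced designs the estimates equal the classical ANOVA
method-of-moments forms (tested to 1e-6), and on an unbalanced fixture
they match lme4 to six decimals.

Entry-mean reliability is `i2 = s2_g / (s2_g + s2_e / r)` with `r` the
harmonic mean of per-genotype replicate counts. The division by `r` is
the reading of the formula that reproduces published reliability tables
for comparable inducer trials; note that such tables print *rounded*
variance components, so the recomputed `i2` can differ from a printed
value by one unit in the last decimal.

## GWAS

The single-locus engine is a mixed linear model with a VanRaden genomic
relationship matrix K and the first three principal components of the
centered marker matrix as covariates. The polygenic/residual variance
ratio is estimated once on the null model through the eigendecomposition
of K (restricted likelihood profiled over the ratio) and reused for every
SNP — the P3D shortcut, standard MLM practice and two orders of magnitude
cheaper than per-SNP REML at these sample sizes. Each SNP then gets a
weighted-least-squares Wald t-test with n − rank(fixed) degrees of
freedom. With K = I the scan collapses exactly to per-SNP OLS (tested to
1e-6), and null p-values are uniform (KS < 0.05 at 5,000 SNPs).

The multi-locus engine is a forward–backward conditioned scan: scan all
SNPs with the currently selected set as fixed covariates, add the most
significant SNP if it passes the Bonferroni threshold
`-log10(0.05 / n_snps)` (ties broken by (p, chrom, pos)), then jointly
re-test the selected set and drop members that fall below the threshold;
terminate when the set stabilizes (cycle detection warns and stops). This
plays the role full multi-locus association machinery (FarmCPU/BLINK
style) plays in GWAS-assisted prediction — producing a sparse,
conditionally significant SNP set — without reproducing their binning/LD
internals, which downstream stages never consume. Whole/shared set logic
(union/intersection across engines) is therefore exercised with two
engines.

Per-SNP variance explained is `PVE = Var(xβ̂) / (Var(xβ̂) + σ̂²_res)`
where σ̂²_res is the scan's per-SNP residual variance mapped back to the
data scale (whitened-scale estimate times the mean eigenvalue of the null
covariance); for a kinship scan it is the total non-marker variance
(polygenic + residual), the conservative denominator.

## Genomic prediction

**rrBLUP.** `y = mu + Xb + Zu + e` with u ~ N(0, I σ²_m); markers are
column-centered at their training means. λ = σ²_e/σ²_m is REML-estimated
via the eigendecomposition of ZZ', and `u = Z'(ZZ' + λI)⁻¹(y − Wβ̂)`.
With X empty this is plain rrBLUP; a SNP used as a fixed effect is removed
from Z to avoid exact collinearity. Predictions for training or new lines
are `mu + X b + (Z − z̄)u`, identical to GBLUP under the VanRaden kinship
built from the same markers (tested to 1e-6 on a 50 x 500 DH-family
fixture). A note on identifiability: in small *unstructured* panels the
kinship spectrum is nearly flat and λ is weakly identified (REML can run
to a boundary); in family-structured panels — the intended use — the
spectrum is spread and λ is recovered within a factor of 1.5 (median over
seeds) at genomic h² = 0.5.

**BayesB.** Same linear structure with marker-specific variances and a
point mass at zero: δ_j ~ Bern(1−π), u_j | σ²_j ~ N(0, σ²_j),
σ²_j ~ scaled-inv-χ²(ν=5, S), π ~ Beta(κπ₀, κ(1−π₀)) with prior-mean
exclusion π₀ = 0.95 and κ = 10. The marker scale S is set so the prior
genomic variance is half the phenotypic variance; the residual prior
likewise. The Gibbs sampler (default 1,000 burn-in, 6,000 iterations,
thinning 1, posterior means reported) updates fixed effects, per-marker
indicator/effect/variance (effect marginalized over the indicator for the
inclusion draw), π, and σ²_e; the inner loop is numba-compiled and the
chain is bit-reproducible from the seed. A non-finite state aborts with
the iteration index. Setting `fix_pi=0` plus `common_marker_variance=True`
reduces the model to a Bayesian ridge, which matches rrBLUP effects at
r > 0.98 — the limiting-case oracle. Chain stationarity is monitored with
a Geweke z-score on the σ²_e chain.

**Multi-trait SVD wrapper.** Trait columns are centered and scaled to
unit variance before the SVD (the scaling choice is not dictated by the
field; unit-variance scaling keeps traits with very different units — days
vs cm² magnitudes — from dominating V, and is flagged for sensitivity
analysis). Each column of Y* = YV is fitted independently by the base
solver; effects and predictions are back-rotated with V' and un-scaled.
V columns are sign-fixed (largest-magnitude entry positive) for
reproducibility. Complete cases are required, matching the usual
multi-trait training-set restriction. The fixed-SNP set for a
multi-trait fit is the union of per-trait detected SNPs, since a single X
serves all traits. Duplicated traits reproduce the single-trait fit
(r > 0.9999), and the transform round-trips (ŶV = Ŷ*) to 1e-8.

**Tree baselines.** RandomForest/xGBoost adapters over scikit-learn and
xgboost, tuned by a small seeded grid (feature fraction and leaf size for
RF; depth and learning rate for xGBoost) under 5-fold inner CV minimizing
MSE.

## Cross-validation and validation

Lines are shuffled once per repeat across the whole training set (a
within-family stratified option is a possible extension; whole-set
shuffling matches the reference design) and split into k folds; every
line is held out exactly once per repeat. Single-trait methods use each
trait's observed lines, multi-trait methods the complete cases. For
GWAS-assisted variants both engines run on the training folds of each
split only; the per-split detected sets are logged, and a test replays an
engine on a logged partition to prove the log is faithful (no leakage).
Predictive ability is the Pearson correlation between held-out BLUEs and
predicted genotypic values, with its t-test p-value; a constant vector
raises rather than silently scoring 0. Method comparisons use one-way
ANOVA on the per-fold PA values (5 folds x 5 repeats = 25 replicates as
the replication unit) followed by Fisher's LSD at α = 0.05 with a
compact-letter display (deterministic, descending means); an optional
filter restricts the comparison to splits where shared SNPs were
detected. Test-set validation refits every method on the full training
set (GWAS included) and scores the unseen MAGIC lines; train/test overlap
is an error.

## Synthetic populations

The generator emulates a multi-family inducer program: 9 fully homozygous
founders (per-SNP founder allele frequencies U(0.25, 0.75), ≥95% of SNPs
segregating), 10 chromosomes x 700 SNPs on a 150 cM map, 23 biparental DH
families with sizes 5–48 (334 lines; founders are appended to the
training panel), and an 11-line 8-way MAGIC test set. Meiosis is Haldane:
Poisson crossover counts with mean L/100 per chromosome, uniform crossover
placement, no interference; a DH line is one recombinant gamete doubled,
so simulated genotypes are homozygous ({−1,1}) until the missingness
injector (default 2%) runs. MAGIC funnels are randomized per line (the
funnel order is not part of the emulated design), and founder ancestry can
be tracked locus-by-locus; shares converge to 1/8.

Traits: DTF, PHT, PBL polygenic (300 minor QTL each); HIR oligogenic with
2 major QTL carrying 50% of its genetic variance plus 50 minor QTL.
Genetic variances and plot-level heritabilities are calibrated to the
magnitudes of published inducer field trials (e.g. DTF 5.27/1.78), and
genetic correlations are weak (|r| ≤ 0.25; DTF–HIR = −0.228). Correlations
are induced by Cholesky-mixing the standardized minor-polygenic scores
across traits after whitening their sample correlation, with the minor
correlation inflated by 1/sqrt((1−f_i)(1−f_j)) so the *total* genetic
correlation hits the target despite trait-specific major QTL; each major
score is residualized against the mixed minor components because family
structure correlates any two marker scores. With at most one
major-QTL trait the realized correlations are exact by construction
(within-sample). The ground-truth table records genetic values, QTL
positions/effects, the full effective-effect matrix (the genetic values
reconstruct exactly as Zα plus a constant), realized correlations, and
the design effects.

The field design is a complete years x blocks factorial (default 2 x 2)
with trait-specific year and block-in-year shifts (drawn at σ_e and
0.5 σ_e scale) and iid Gaussian plot residuals scaled to the target
plot-level h²; a fraction of records (default 30%) is deleted at random
to create the unbalancedness the BLUE/REML stage must handle.

What the simulator does **not** emulate: genotyping error, LD-based or
haplotype imputation structure (missingness is uniform), selection or
drift within families, genotype x year interaction, spatial field trends,
and non-additive (dominance/epistatic) trait architecture. Passing tests
therefore demonstrate correctness of the estimators and the pipeline
logic under an additive, well-specified world — not robustness to those
real-data features.

## Problem sizes in the test suite

The suite runs the full default study (343 training lines, ~6,800
post-filter SNPs) for the pipeline-level checks: one five-fold CV of
ST_rrBLUP over all four traits, and ten seeds of the
ST_rrBLUP-vs-ST_GWAS_rrBLUP contrast on HIR. Statistical calibration uses
50-seed batteries at n = 300 (power, family-wise error) and single runs at
n = 2,000 (PVE, REML recovery, heritability and correlation calibration).
BayesB fixtures are 50–200 lines x 100–200 markers with 1,500–3,000
iterations — enough for the limiting-case and detection oracles at a few
seconds per chain.

## Known limitations

- The multi-locus scan is a surrogate: it preserves the detected-set
  interface and the conditional-significance property of multi-locus
  engines, not their exact output.
- Imputation is locus-wise (major-allele or frequency draw); defensible
  for homozygous DH panels with low missingness, wrong for heterozygous
  material.
- P3D fixes the variance ratio at the null fit; SNPs with very large
  effects would deserve exact per-SNP REML.
- The multi-trait model fits transformed traits independently, which is
  exact only when the transformed residual covariance is diagonal; it is
  the standard SVD approximation, not a full multivariate REML.
- LSD assumes equal replication per method and treats fold-level PA
  values as independent replicates, ignoring fold overlap correlation —
  the conventional, slightly anti-conservative choice.
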
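# Methods

This note documents the statistical models implemented in `gcovpipe`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Phenotype model and transformation

Questionnaire traits are integer summary scores (defaults: an ADHD-symptom
subscale with range 0–10 and a social-communication checklist with range
0–24), strongly right-skewed. Variance-component estimation assumes
multivariate normality, so each measure is processed as:

1. OLS residualization of the raw score on intercept, sex, exact age, and two
   ancestry-informative principal components (rows with missing covariates
   dropped and logged);
2. rank-based inverse-normal transformation with Blom offsets,
   `Phi^-1((r - 3/8) / (n + 1/4))`, average ranks for ties.

Integer scores guarantee heavy ties, so the tie convention is load-bearing:
average ranks keep the transform well defined and symmetric. After the
transform the phenotypic variance is ~1, which makes the genetic variance
ratio Var_g identical to SNP-h² and the bivariate genetic covariance equal
to `r_g * sqrt(h²_1 h²_2)`.

The effective number of independent measures uses the eigenvalue-spectrum
estimator `Meff = 1 + (M-1)(1 - var(lambda)/M)` (sample variance of the
eigenvalues), rounded to the nearest integer, followed by the Šidák step
`alpha_e = 1 - (1 - alpha)^(1/Meff)`. Five effective measures at family
alpha 0.05 give the experiment-wise rate 0.0102.

## Genetic relationship matrices

GRM entry for individuals j, k:

    G_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with `p_i` the in-sample alternate-allele frequency and `M_jk` the count of
SNPs observed in both individuals. Missing dosages are handled
pairwise-complete (not mean-imputed), matching the per-pair counts stored in
the GCTA `.grm.N.bin` companion file. Monomorphic SNPs carry no information
and are skipped with a warning. Relatedness pruning at cutoff 0.025 is
greedy: repeatedly drop the individual in the most offending pairs, ties
broken by lexicographically smallest id — deterministic, and on small
instances it reproduces the maximum feasible subset found by exhaustive
search.

Gene-set partitioning is 1-based inclusive: a SNP is in-set iff it lies
within `[start - flank, end + flank]` of any listed gene on the same
chromosome (default flank 50 kb). BED files are converted at the I/O
boundary (0-based half-open on disk).

## REML engine

All variance components are estimated by average-information (AI) REML with
step-halving and an EM fallback (`sigma² <- sigma² + sigma⁴ (y'PVPy -
tr(PV))/N`) whenever an AI step leaves the feasible region or decreases the
restricted likelihood. Convergence: |Δ log-lik| < 1e-8 or 100 iterations;
non-convergence is flagged on the result, never silent. Variance components
are constrained non-negative (floored at 1e-8 of the phenotypic scale);
covariance components are unconstrained. Standard errors come from the
inverse AI matrix via the delta method; reported `r_g` is clamped to
[-1, 1] with a log note when estimation overshoots.

Two backends share the update logic:

* a dense backend over explicit N×N structure matrices (partitioned fits,
  partial-overlap bivariate fits), costing one Cholesky + inverse per
  iteration;
* a block-diagonal backend used after rotating into the eigenbasis of a
  single GRM, where every structure becomes (T×T block) × (per-eigenvalue
  weight). This is exact — not an approximation — whenever all components
  share the GRM's eigenvectors, i.e. univariate fits and complete-overlap
  bivariate fits, and reduces each iteration to O(n).

Likelihood-ratio tests for one variance component on its boundary use the
50:50 `chi²_0/chi²_1` mixture; the bivariate genetic covariance (sign
unconstrained) uses a plain `chi²_1` against the refit with the covariance
pinned to zero. If a genetic variance sits at the zero boundary, `r_g` is
reported as undefined with an explanatory note rather than as a 0/0 ratio.
Two numerically identical traits are detected up front and returned as the
exact degenerate result (`r_g = r_e = 1`); the joint covariance is singular
there and the likelihood unbounded, so iterating would only crawl toward
that boundary.

## Pathway meta-analysis

For each gene set, each measure is fit with three components (set-GRM,
noset-GRM, residual) and the set component is tested by the boundary LRT
against the noset-only reduced model. Evidence across K measures is
combined by a quadratic-form homogeneity statistic on correlation-adjusted
z-scores:

    Q = z' R^-1 z,   z_i = max(Phi^-1(1 - p_i), 0)

where `p_i` is the boundary-mixture p-value and R the phenotypic
correlation matrix among the measures (eigenvalue-floored at 1e-6 with a
log note when regularization bites). The inversion recovers the signed LRT
root exactly, because the mixture p equals the one-sided normal p of that
root; `p = 1` encodes an estimate at the zero boundary and maps to `z = 0`.

Under the null, each `z_i` is a positive-part normal, so Q is *not*
chi-square distributed; the default reference is a seeded Monte Carlo draw
of `max(MVN(0, R), 0)` quadratic forms (200,000 draws), which keeps the
combined p calibrated under both the inter-measure correlation and the
boundary atom. When every measure sits at its boundary (Q = 0, an atom with
non-negligible mass under positive correlation), a seeded randomized
completion spreads that atom's probability over the top of the unit
interval, preserving exact uniformity of the null p — the classical device
for discrete atoms. A plain `chi²_K` reference is available as
`rule="chi2"`; it is conservative under the null and kept for comparison.
Bonferroni adjustment defaults to 50 pathways (hallmark-collection scale).

Permutation control for gene-set size: random sets matched to the target on
per-length-decile gene counts and total length (±10%), each scanned and
combined identically; `empirical_p = (1 + #{Q_perm >= Q_obs})/(n_perm + 1)`,
floored at 1/(n_perm+1) by the add-one rule (1/201 at the default 200
permutations).

The age/trait meta-regression fits `var_set_i = b0 + b_age * age_i +
b_trait * trait_i (+ b_txa * age_i * trait_i) + u_i + e_i` with known
sampling covariance `V = D R D` (D = diag of GREML standard errors) plus a
random-intercept variance tau² estimated by REML (profiled on the log
scale, boundary at zero included). Traits are coded 0/1 in alphabetical
label order. The interaction is tested by an ML likelihood-ratio test
between the nested fixed-effect models. At tau² = 0 the estimates equal the
closed-form GLS solution. The `D R D` form is an approximation to the true
sampling covariance of correlated variance-component estimates; no attempt
is made to derive the exact covariance.

## Polygenic scoring

Clumping is greedy and p-value ordered (r² > 0.25 within ±500 kb removed;
ties in p broken by chromosome and position; duplicate SNP ids keep the
smaller p). Scores are sums of effect-allele-aligned dosages weighted by
log-odds, with missing dosages contributing `2 * freq * effect`, built per
p-value threshold from the default grid {0.01, 0.05, 0.1, 0.2, 0.3, 0.4,
0.5, 1.0} inside the open interval (0.001, 1], and Z-standardized.
Effect-allele alignment complements the dosage (2 - x) when the effect
allele is the panel reference, making scores exactly invariant under
allele-label flips.

Cross-sectional association is OLS of the rank-normalized measure on the
standardized score, reported as adjusted R². Longitudinal association uses
untransformed scores: a Gaussian linear mixed model (fixed PGS, sex,
centred age; random intercepts and age slopes; REML) for the 0–10 trait,
and a Poisson random-intercept model with a hand-written Laplace
approximation of the marginal likelihood for the 0–24 trait (no installed
package exposes a Laplace-likelihood Poisson GLMM with an extractable
log-likelihood). PGS×age interactions are tested by ML likelihood-ratio
tests. Individual-level nonparametric bootstrap (individuals resampled with
all their occasions, default 500 replicates) yields parametric 95% CIs
(point estimate ± 1.96 × bootstrap SD). The marginal R² is the
fixed-effects share of total variance, `var(Xb) / (var(Xb) + var(Z u) +
sigma²)`. Singular random-effect covariances trigger a logged refit with a
diagonal structure; a bootstrap with fewer than two successful resamples is
flagged degenerate rather than silently reported.

## Polygenic power and covariance model

The closed-form model treats the score as built from m independent SNPs of
which m_c are causal, with liability-scale effects `gamma ~ N(0, h²_l/m_c)`
per standardized genotype. A case/control discovery of n1 individuals with
case fraction P and prevalence K maps to the observed 0/1 scale through the
liability-threshold factor `C = z P(1-P) / (K(1-K))` (z = normal density at
the threshold), with estimate sampling variance `tau² = P(1-P)/n1`. A SNP
enters the score when `|beta_hat| > tau * Phi^-1(1 - P_T/2)`; truncated
second moments of the causal and null effect distributions then give the
expected score variance and score–trait covariance, hence the expected
target R², the non-centrality `n2 R²/(1-R²)` of the association test, and
its power at alpha. Because R² is proportional to the squared genetic
covariance with covariance-free factors, the inversion from an observed R²
is closed-form; the 95% CI propagates the sampling variance of R²
(`4R²(1-R²)²/n + 2/n²`) by the delta method. The expected R² matches the
expectation of the *adjusted* regression R², whose correction removes the
1/n noise inflation of the raw R².

Defaults: 100,000 causal SNPs per disorder among 150,000 independent score
SNPs — a realistic post-clumping count for HapMap3-scale summary statistics
at r² < 0.25 / ±500 kb. In the two cross-dimensional power scenarios the
trait–disorder covariance is set to half the uni-dimensional ADHD-dimension
covariance (0.10/2 = 0.05) for both discovery designs; with the alternative
reading (half of 0.072) the ADHD-discovery scenario's power falls far below
the published scale, so the package documents the 0.10/2 scenario as its
default. Only quantitative targets are modelled.

## Synthetic-data generator

What it emulates: a post-QC genotyping chip (Hardy–Weinberg dosages,
MAF ≥ 0.01, 22 autosomes, strictly increasing positions); non-overlapping
gene intervals with exponential lengths; two longitudinal traits at their
assessment ages (7/10/12/13/17 and 8/11/14/17 years by default) whose
per-SNP effect vectors are multivariate normal with an age-gap-decaying
genetic correlation kernel (`exp(-0.06 |Δage|)` within trait, ×0.9 across
traits; residuals `exp(-0.15 |Δage|)`, ×0.5 across — separable products of
positive-definite kernels, hence valid correlation matrices); per-measure
genetic values rescaled to hit the h² targets exactly in-sample (a scalar
per measure, so all correlations are preserved); optional gene-set
enrichment routing a stated fraction of genetic variance through causal
SNPs inside set genes ± flank; raw scores produced by monotone binomial
quantile maps (Binomial(10, 0.25) and Binomial(24, 0.12)) that reproduce
the right skew and leptokurtosis of real questionnaire data without
item-level modelling; and case/control discovery GWAS generated
analytically — true liability effects converted to observed-scale log-odds
plus Gaussian noise at the design-implied standard error — because the
downstream scoring model consumes only (effect, p). When a trait–disorder
genetic covariance is requested, shared causal SNPs' liability effects are
drawn correlated with the trait's effects to hit the target covariance in
expectation, with a validation error when the request exceeds what the
liability h² allows.

What it does not emulate: linkage disequilibrium (SNPs are independent
given frequency), population stratification or cryptic relatedness
(individuals are i.i.d., so the ancestry PC covariates are pure noise),
sample dropout over age, item-level response processes, strand-ambiguous
alleles, and the X chromosome. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to LD structure or confounding in real cohorts.

## Problem sizes and numerical choices in the test suite

Parameter-recovery checks run at n = 2000 individuals × 5000 SNPs
(univariate h² = 0.4 and bivariate r_g ∈ {0, 0.5, 1}, all via the
eigenbasis fast path) and n = 1200 × 2000 for the three-component
partitioned fit (30% set share of h² = 0.4); these sizes give standard
errors small enough for 2-SE recovery to be informative while keeping the
suite inside a desk-scale budget. Null calibration uses 200 replicates at
n = 200 × 400 (boundary LRT rejection rate), 200 synthetic correlated
scans (combined-p uniformity), and a 200-permutation matched gene-set run
at n = 150 × 500. The end-to-end consistency check compares the mean
adjusted R² of 20 fully simulated GWAS→clump→score→regression replicates
(n = 2000 × 1200) against the closed-form forward model within Monte-Carlo
error. Tolerances follow the underlying sampling theory (binomial bounds
for frequencies, 2 estimated SEs for recovery, Kolmogorov–Smirnov at 0.01
for uniformity, 1e-12/1e-8/1e-3 for exact oracle equivalences).

## Known limitations

* Bivariate fits with partial overlap use the dense backend and scale as
  O((n1+n2)³) per iteration; very large partial-overlap designs would need
  a sparse or stochastic trace estimator.
* The Poisson GLMM uses a one-dimensional Laplace approximation; with very
  small counts and large random-intercept variance the likelihood (and
  hence LRT) carries the usual Laplace bias, and no marginal R² is
  reported for it.
* The `D R D` sampling covariance in the meta-regression and the use of
  phenotypic correlations as the dependence structure for combined tests
  are approximations inherited from the analysis design.
* The power model ignores LD between score SNPs and assumes equal per-SNP
  causal variance; its score-SNP count is a stated default, and the
  covariance inversion is exact only relative to that architecture.
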
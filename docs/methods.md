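# Methods

This note documents the statistical models implemented in `ewaskit`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Probe-wise association models

Methylation is modeled on the 0–100 percent scale so that regression
coefficients read directly as percentage-point differences between groups
(or per unit of a continuous score). For each probe the model is ordinary
least squares with a shared design matrix — intercept, the tested
predictor, and adjustment covariates (categoricals dummy-coded, first level
dropped). The probe loop is vectorised: one factorization of the design
serves every probe, which is what makes 5000-fold permutation reruns
affordable. Probes with zero variance are skipped with the reason
`constant outcome`; a rank-deficient design is rejected outright rather
than silently dropping columns.

Beta values (proportions) rather than M-values are modeled throughout.
This keeps effect sizes interpretable in percentage points at the cost of
mild heteroskedasticity near the interval boundaries; the covariate-
adjusted tests remain well calibrated in the generator's operating range
(see CI coverage below).

Cell-composition proportions sum to one per sample, so only k−1 of the k
proportion columns may enter a model with an intercept; the pipeline driver
drops the last column. The polygenic-score model excludes the smoking
score by default: a genetic exposure is not confounded by smoking behavior
the way diagnosed case status is, and including it would adjust away signal
rather than confounding.

### Twin (clustered) variant

For twin designs the OLS point estimates are kept and the variance is
replaced by the CR1 cluster-robust sandwich: multiplier
`G/(G−1) · (N−1)/(N−K)` on the clustered meat matrix, with the t reference
on `max(G − K, 1)` degrees of freedom. CR1 is the conventional default
when the source analysis names only a software package, and the estimator
is recorded in the results metadata. Singleton clusters are allowed (each
its own cluster) with a warning. Note the direction of the correction
depends on the design: a cluster-level predictor with positively correlated
outcomes inflates the sandwich SE relative to the classical one, while a
within-pair discordant exposure (the usual MZ-twin design) deflates it —
the within-pair contrast cancels shared variance. The test suite pins both
directions.

## Derived covariates

**Smoking score.** `s_i = Σ_j w_j m_ij` over the weight panel's probes
present in the matrix, where `m_ij` is the beta value for sites
hypermethylated in smokers and `1 − beta` for hypomethylated sites, so
positive contributions always point in the exposed direction. The score is
reported with the count of probes used; probes absent from the matrix are
tolerated (and counted), zero overlap is an error. No standardization of
beta before weighting by default — the simplest reading of a weighted
score — with a `standardize` switch for the z-scored variant, recorded per
run. The packaged 183-row weight panel is synthetic (ids `cgS…`), shipped
so examples and tests run self-contained; real analyses supply a published
panel in the same three-column TSV layout.

**Methylation PCs.** SVD of the mean-centered, unscaled beta matrix with
samples as observations, on the post-QC, pre-smoking-removal probe set.
Scores are returned with their variance shares and an absolute-correlation
report against the phenotype columns, which is how cell-composition and
batch structure are diagnosed. Sensitivity analysis: refit the EWAS with
1..k PCs appended and report the Spearman correlation of the coefficient
vector against the base model, overall and on a supplied probe subset.

## Quality control

Order: detection filter → PC outliers → sex check → analysis probe subset;
the order is recorded in the QC report (where the source pipeline leaves it
unstated, this is the adopted convention). The detection filter removes
samples whose fraction of failed detections (p > 0.05) is strictly greater
than 1 %, then recomputes probe failure fractions over retained samples and
removes probes strictly above 1 % — strict inequalities, per the ">1 %"
rule it implements. PC outliers are samples beyond 2 SDs on *both* PC1 and
PC2 (conjunction); PCA is mean-centered, unscaled, over all probes. The
sex check partitions samples on the first principal coordinate of the
X-chromosome probes at the largest gap in the sorted scores (no fixed
threshold is published for this check); clusters are mapped to sexes by
majority vote, and degenerate partitions (single cluster, gap below half a
score SD, clusters mapping to one sex) warn and make no calls rather than
guessing. SNP-control-probe concordance is the within-pair Pearson
correlation over the trimodal `rs` probes, flagging pairs below 0.9.

## Permutations and family-wise error

Only the predictor column is permuted; covariates stay attached to their
samples, so each permutation reruns the identical model under a random
case/control reassignment of the original group sizes. Covariates are not
re-derived per permutation — smoking scores and PCs are functions of the
methylation matrix, not of the labels, so they are label-invariant anyway.
The family-wise threshold is the lower empirical order statistic at rank
`ceil(α·n_perm)` of the ascending minimum-p vector — no interpolation, so
the threshold is always an observed value and exactly reproducible.
Empirical region p-values use the strict-count convention
`#(perm < observed)/n_perm` (0 is reported as such, to be read as
"< 1/n_perm"); a `pseudo_count` flag provides the `(c+1)/(n+1)` variant.
Stored full p-matrices are written as little-endian float64 with a JSON
header, since `n_perm × m` doubles dominate storage.

## Region statistics

Brown's method scales Fisher's statistic by the correlation structure:
`cov(−2 ln p_i, −2 ln p_j)` is approximated by the Kost–McDermott
polynomial `3.263ρ + 0.710ρ² + 0.027ρ³`, where ρ is the Pearson
correlation of the two probes' beta values across all analyzed samples
(cases and controls pooled; which subset the source used is unstated, and
pooled is recorded in metadata). At ρ = 0 this is exactly Fisher's method;
at ρ = 1 the polynomial sums to 4 and the combined p collapses to the
single-test p. Negative correlations contribute negative covariance terms,
but the summed covariance is floored at zero (falling back to Fisher, and
flagged) so the effective degrees of freedom never exceed 2k — without the
floor a net-negative sum would imply f > 2k and an anti-conservative test.
Zero p-values are clamped to the smallest positive double with a warning.

Sliding windows are half-width semantics: probe position ± w, closed
interval, same chromosome, for w ∈ {100, 200, 500, 1000, 2000, 5000} bp
("window size" could denote half-width or total span; half-width is
adopted and flagged here). Every probe seeds a window; windows with fewer
than two probes are not emitted, and identical probe sets from adjacent
seeds are deduplicated within each w before threshold comparison so minima
are not double counted. Per-window Brown scale factors (c, f) are
precomputed once from the observed correlations and reused across
permutations — the permuted quantity is the p-vector, not the correlation
structure. Per-window-size thresholds are the 5th percentile of the
per-permutation minimum combined p. The significant set is reduced
greedily: ascending p, drop any region sharing a probe with an already
retained one; the output is asserted probe-disjoint on every run.

The external-region scan (e.g. GWAS-nominated intervals from BED, 0-based
half-open on disk, converted to 1-based inclusive on read and the
conversion logged) computes Brown combined p per region with ≥ 2 probes
for both the case–control and polygenic-score EWAS, a Bonferroni level of
α divided by the number of testable regions, and empirical p-values by
re-combining the stored permutation p-vectors per region.

## Enrichment

Feature overlap is the two-sided Fisher exact test (p = sum of all tables
with point probability ≤ observed, verified against an exhaustive
hypergeometric oracle) with the sample odds ratio, Bonferroni-corrected
over the number of features tested. Pathway enrichment fits, per pathway,
`member(gene) ~ 1 + in_test_list(gene) + probe_count(gene)` by maximum
likelihood over the gene universe (genes with ≥ 1 analyzed probe and ≥ 1
pathway; pathway sizes filtered to [10, 2000]). The probe-count covariate
is the method's point: genes with more array probes are more likely to
contain a significant probe by chance, and a naive hypergeometric test is
badly inflated under probe-count-driven selection (measured at ~65 % false
positives at α = 0.05 in the acceptance run, versus ~5 % for the adjusted
test). Probe counts enter untransformed by default with a log-count
switch. Under separation or non-convergence the fit falls back to Firth's
bias-reduced logistic regression (Jeffreys-prior score correction) and the
row is flagged — Firth keeps estimates finite and, crucially, lets a
pathway made redundant by a collinear head term test non-significant in
the grouping step, which a ridge fallback does not. Grouping is the
iterative head/explained algorithm: most significant pathway becomes a
head, every remaining significant pathway is refitted with head-membership
as an extra covariate, and those whose test-list coefficient p rises to
≥ 0.05 are marked explained by the head, until all pathways are heads or
explained.

## Genetics

Genotype QC order: samples by missingness (> 5 %), SNPs by missingness,
then HWE (1-df chi-square, p < 0.001 — a threshold is named by convention,
not a test; the chi-square is recorded in the report), MAF ≤ 5 %, and a
minimum of five observations per genotype group — checking only the two
observed groups when the rare homozygote is entirely absent. The cis-mQTL
scan fits the additive model per SNP–probe pair within 500 kb (SNP
position to the probe's single manifest coordinate), methylation on the
0–100 scale, with age, sex and the first two genotype-derived PCs as
covariates; the probe loop per SNP is vectorised like the EWAS. Polygenic
scores are `Σ_k w_k · dosage_k` with the effect allele aligned to the
alternate allele (dosage flipped when the effect allele is the reference,
SNP dropped with a warning when it matches neither); missing genotypes are
mean-imputed at 2·MAF.

Co-localization uses Wakefield log-ABFs with prior effect SD 0.15 for
quantitative traits and 0.2 for case–control, and per-SNP priors
p1 = p2 = 1e-4, p12 = 1e-5 (the conventional defaults, exposed in
`ColocPriors`). All hypothesis sums run in log space; the H3 cross-sum
uses the factorization `Σ_{i≠j} = Σ_i Σ_j − Σ_{i=j}` computed with
`log1p`, verified against the explicit double sum. Classification gates:
PP3+PP4 > 0.99 for a co-localized signal, additionally PP4/PP3 > 1 for
same-variant and > 5 for convincing; PP3 = 0 with positive PP4 is treated
as an infinite ratio.

## Meta-analysis and elementary statistics

Fixed-effect pooling is inverse-variance (`w = 1/SE²`); random effects use
DerSimonian–Laird `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))`. Both are
reported but the fixed model is the inferential one — with two or three
cohorts τ² is too poorly estimated to trust. The sign test is the exact
one-sided binomial tail `P(X ≥ s | n, ½)`, summed in log space so tails at
n > 1000 (down to ~1e-261) remain accurate; the one-sided convention is
adopted because the concordance statistics it reproduces are one-sided
tails. Mann–Whitney uses exact enumeration for tie-free samples with
min(n) ≤ 8 and the tie-corrected normal approximation without continuity
correction otherwise (continuity is a flagged choice, not a default).
Spearman is Pearson on mid-ranks; constant vectors are an error, not NaN.

## The synthetic-data generator

What it emulates: bimodal baseline methylation (mixture of low/high/mid
Beta draws); cell-type structure as sample Dirichlet proportions times
cell-type reference profiles (a fifth of probes strongly cell-variable) —
reproducing the confounding that composition covariates remove without
implementing deconvolution; batch offsets and residual noise on the logit
scale, transformed back and clipped to [0.001, 0.999] so planted effects
can be specified additively in percentage points post-transform; a latent
smoker indicator with higher prevalence in cases (0.55 vs 0.25) driving
planted smoking probes — the smoking-confounding structure the smoking
score exists to remove; DMR blocks as a shared per-block latent factor
scaled per probe to a target pairwise correlation; MZ twin pairs sharing
age, sex, batch, genotypes and a tunable fraction (`twin_correlation`,
default 0.5 — the within-pair correlation of twin methylation is not
something a single published value pins down, so it is a parameter, not a
constant) of the residual variance; Hardy–Weinberg genotypes with planted
per-allele methylation shifts; and paired GWAS summary statistics whose
marginal effects follow `ρ^|i−causal|` LD decay with sampling noise drawn
under the same correlation and variances `1/(2Nf(1−f))`.

Defaults are the operating points the analyses assume: `noise_sd = 0.2` on
the logit scale (~5 pp residual SD at mid-methylation probes — the level
implied by percentage-point effects of 1–3 pp reaching p < 1e-7 at
n ≈ 675), 7 blood cell types, probe spacing 1 kb. Planted-effect probes
draw mid-range baselines (U(0.35, 0.65)) so percentage-point shifts stay
inside the unit interval; an effect that would push the expected value
outside [0, 1] is rejected with an explicit message, and an mQTL shift
that clips more than 1 % of values warns that the realized slope is
attenuated (declare the effect to `generate_cohort` so the target probe
gets a mid-range baseline). A single `default_rng(seed)` stream drives
each generator call and the seed is recorded in the truth JSON;
regeneration is byte-identical.

What it does not emulate — and hence what passing tests do not show about
real data: probe-specific measurement error profiles and type I/II design
chemistry, realistic LD panels (LD is exponential in SNP index),
chromosome-scale genome structure, population stratification, age- or
sex-associated methylation drift, and non-blood tissue. Calibration and
recovery results transfer to real arrays only to the extent those features
are second-order for the statistic under test.

## Numerical choices and degenerate inputs

Zero p-values are clamped to the smallest positive double (warned);
combined p-values are floored at the same value rather than returning 0.
`Var ≤ 0` in Brown's scaling falls back to Fisher and is flagged.
Quantile ranks use `ceil` with a floor of 1. The coloc H3 `log1p`
factorization degenerates when all cross mass sits on the diagonal (two
SNPs, identical ABFs); that case returns −inf for H3 core, i.e. PP3 = 0.
Permutation counts too small to resolve the requested quantile warn and
return the smallest observed minimum. All stage outputs carry the
producing stage, config hash and seed in the run manifest.

## Problem sizes

The packaged demo and the acceptance script use desk-scale sizes chosen to
exercise every code path with stable statistics: 100–500 probes and
200/arm for recovery and DMR replicates (100 replicates each), 1000
independent probes × 500 permutations for FWER calibration, 500 simulated
pathways over 1200 genes for the enrichment bias check, and 20–50 SNP
regions for co-localization. These are the package's validation operating
points; the implementation itself is vectorised for array-scale inputs
(450K probes, thousands of samples).
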
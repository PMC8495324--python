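# Methods

This note documents the statistical models, the synthetic-data design and
the numerical choices behind `peamix`. It is the reference for what the
package computes and for what its passing tests do and do not establish.

## The scientific setting

Pea (*Pisum sativum*) intercropped with cereals is usually the weaker
competitor, and genotype yield responses in mixed stand (MS) correlate only
moderately with responses in pure stand (PS). A breeding programme must
therefore decide where and on what to select. The package compares four
strategies for improving pea grain yield in MS:

1. direct phenotypic selection on yield in MS;
2. indirect phenotypic selection on yield in PS;
3. indirect selection on a linear index of PS-measured traits (plant height
   at flowering onset, flowering date, PS yield);
4. genomic selection trained on MS-yield BLUPs.

Strategies are compared through three relative-efficiency (E_R) statistics,
all in percent of direct MS selection:

* **heritability-based (Falconer)**: `E_R = (H_ind / H_dir) · r_g · 100`,
  with `H` the square root of line-mean broad-sense heritability of each
  criterion and `r_g` the genetic correlation between criteria;
* **correlation-based**: `E_R = (r̄_ind / r̄_dir) · 100`, with `r̄` the
  phenotypic correlation between criterion values in one year and MS yield
  in the other year, averaged over the two year assignments;
* **gain-based**: `E_R = (G_ind / G_dir) · 100` from realized year-swap
  gains — top 2 of 23 lines per RIL population selected in one year, their
  MS-yield advantage over the six parents measured in the other year.

## Trial design and estimators

The field design is a split plot repeated over two cropping years: growing
condition (MS/PS) on main plots, 144 inbred lines (6 biparental RIL
populations × 23 lines + 6 parents) on subplots, three blocks nested in
years.

**ANOVA.** Four balanced-design models are supported: lines + blocks per
condition × year; line × condition split plot per year (condition tested
against condition × block); line × year per condition (lines tested against
line × year, treating seasons as random); and the full
line × condition × year model (condition and condition × year tested
against condition × block within year). Sums of squares are computed from
cell means by inclusion–exclusion; on balanced data they coincide with
type-I least-squares decompositions, which is verified against
`statsmodels.anova_lm` in the tests. Unbalanced tables are refused and
routed to REML.

**Variance components.** The primary estimator equates observed to expected
mean squares (method of moments), which is exactly REML on the balanced
designs used here; negative solutions are truncated at zero and flagged.
The EMS chain for the full model is

    E[MS_G]   = σ²e + n σ²gcy + nY σ²gc + nC σ²gy + nCY σ²g
    E[MS_GC]  = σ²e + n σ²gcy + nY σ²gc
    E[MS_GY]  = σ²e + n σ²gcy + nC σ²gy
    E[MS_GCY] = σ²e + n σ²gcy

with n blocks, Y years, C conditions. An EM-REML routine on the equivalent
mixed model is provided as a cross-check and for unbalanced data; it
matches the method of moments at interior solutions, while at boundary
solutions (a component estimated at zero) REML pools the corresponding
stratum and the two estimators legitimately differ.

**Heritability.** Line-mean broad-sense heritability is
`H² = σ²g / (σ²g + σ²e/n)` within one condition and year, and
`H² = σ²g / (σ²g + σ²gy/y + σ²e/(y·n))` over years. On balanced data both
reduce to `1 − MS_err/MS_line` with the appropriate error mean square, so
an approximate standard error follows from the chi-square sampling variance
of the two mean squares (delta method):
`se(H²) ≈ (1 − H²)·sqrt(2/df_num + 2/df_den)`. The exact formula behind the
study's printed SEs is not reproduced in the source; this approximation
matches the printed values at their two-decimal precision and is used for
reporting only — no pipeline logic branches on it.

**Genetic correlations.** Across conditions, criteria are measured on
different plots so their plot errors are independent and the covariance of
line means estimates the genetic covariance; dividing by the per-condition
genotypic standard deviations gives the cross-condition r_g
(Robertson-style). Estimates outside [−1, 1] — possible with noisy
components — are clamped and flagged. The reported SE uses the classical
approximation `((1 − r_g²)/√2)·sqrt(se(H²_A)·se(H²_B)/(H²_A·H²_B))`. Across
years, `r_g = σ²g / (σ²g + σ²gy)` from the two-year components within one
condition. The u test for comparing two correlations uses the Fisher-z
independent-samples form; it ignores that the two correlations share
genotypes, a known limitation that makes it conservative in neither
direction systematically.

**Selection index.** Forward stepwise OLS of MS-yield line values (averaged
across years) on PS trait line values; a candidate enters when its partial
coefficient has P < 0.05 and the R² increment is at least 0.02. Weights are
the partial regression coefficients of the final joint fit. Candidate
pairs correlated above |r| = 0.95 are refused up front. For its own ANOVA
the index is evaluated per plot with the across-year weights — the source
does not state the level of computation, and the plot-level choice lets the
index be analysed exactly like a trait.

**Reporting conventions.** Gain-based efficiencies are rounded half-up per
year, then the per-year integers are averaged and rounded half-up — this is
the convention that reproduces the printed columns (e.g. 57/71 → 64,
94/81 → 88); raw values are always retained. Selection ties break by
ascending line id.

## Genomic prediction

**Model.** Ridge-regression BLUP: `y = 1μ + Xβ + e`, `β ~ N(0, σ²β I)`,
with markers centred by twice the training allele frequency and not
variance-standardised (the Astle–Balding kinship handles frequency scaling
in the GBLUP formulation). The variance ratio `λ = σ²e/σ²β` maximizes the
restricted likelihood on the spectral decomposition of the
intercept-projected kernel `X Xᵀ`, a one-dimensional bounded search over
log λ ∈ [log 1e−5, log 1e5] (phenotypes are standardized inside the search,
making the estimate exactly affine-invariant). GBLUP solves the same model
through a kinship matrix and is used as the algebraic cross-check: with
`K = X_c X_cᵀ` and a shared λ the two give identical predictions to
numerical tolerance.

**Kinship.** `K = (1/m) Σ_j (x_j − 2p_j)(x_j − 2p_j)ᵀ / (2p_j(1 − p_j))`
with sample allele frequencies; monomorphic markers are skipped. Fully
inbred lines give diagonal entries near 2.

**Cross-validation.** Training always uses one year's MS-yield BLUPs
(shrunken line means) and validates against the other year's observed line
means — an inter-environment design, so predictive abilities are bounded by
the cross-year genetic correlation, not by 1. Three schemes: stratified
intra-population and all-genotypes CV hold out 5 of 23 lines per population
per repetition with the six parents always in training; leave-one-population-out
is deterministic (six splits, 121 training / 23 validation lines). A
strictly constant validation count per line is impossible when
`repetitions × 5` is not a multiple of 23 (e.g. 100 repetitions), so a
greedy balanced draw keeps all counts within one of each other; 92
repetitions give an exactly constant count of 20. Predictive ability is the
Pearson correlation of predicted and observed values computed within
repetition (and within population for the stratified schemes), then
averaged; the ability of repetition-averaged predictions is reported
alongside.

**Threshold tuning.** The missing-rate grid (per marker 1/3/5/10%, per
genotype 10/25/50%) is scored by mean intra-population inter-environment
ability; cells that drop any genotype are inadmissible, and ties go to the
cell retaining more markers.

**GWAS.** Per-marker OLS of line values (averaged across years) on dosage
plus the RIL-population incidence matrix, computed by Frisch–Waugh
residualisation; genomic control divides the chi-square statistics by
`λ_GC = median(χ²)/0.4549` when λ_GC > 1 (never inflates when λ_GC < 1);
Bonferroni threshold α/m. A kinship mixed-model scan (EMMA-style two-step)
is available as an option; the OLS-plus-covariates path is primary because
those are the stated ingredients of the original analysis. Unplaced markers
sit on a fictitious chromosome 99, appended last in Manhattan tables.

## The synthetic-data generator

The generator is first-class, tested code that emulates the study's
structure so every stage runs with no external data.

**Genomes.** Six fully homozygous founders over (by default) 1000 biallelic
SNPs on 7 chromosomes of 100 cM each — marker density and map lengths are
not reported for the real panel, so conventional pea values are used, and
both are configurable (the real panel's 5,909 markers are reachable by
config). RIL meiosis is collapsed to the expected selfing-RIL recombination
fraction between adjacent markers, `R = 2r/(1 + 2r)` with r from the
Haldane map function: marker-level LD structure is exact in expectation,
generation-by-generation selfing is not simulated. GBS-like degradation
adds per-marker and per-genotype missingness and a residual heterozygous
call rate.

**Genetic values.** Each architecture trait (pea yield in MS, pea yield in
PS, seven morphophysiological traits) gets a QTL score (40 markers, normal
effects, 80% of genetic variance by default) blended with an iid polygenic
deviate; the trait × line matrix is then empirically whitened and mixed
through the Cholesky factor of the target correlation matrix (projected to
the nearest PSD matrix by eigenvalue clipping). Realized line-level
correlations therefore match the target essentially exactly, and the linear
map is propagated to the marker effects so genetic values remain exactly
reconstructible as `X_c · effects + polygenic residual`. The QTL share was
set so that genomic predictive abilities on the default scenario match the
magnitude and ordering observed in the study (all-genotypes > intra- >
inter-population); a lower share leaves too much variance in the
non-genomic polygenic remainder, which — unlike real polygenic yield
variation — markers cannot capture at all.

**Correlation targets.** The two yield columns carry the printed
cross-condition genetic correlation (0.42). The morphophysiological targets
are genetic-scale values deattenuated by ≈1.3 relative to the printed
phenotypic correlations, because plot error and genotype × year interaction
attenuate observed line-mean correlations; with this calibration the
simulated trials reproduce the printed observed correlations and the ~60%
R² of the stepwise index. A caveat: the printed two-fold ratio of G×C to
genotypic variance implies a cross-condition correlation of 1/3 under a
symmetric components model and cannot hold simultaneously with r_g = 0.42;
the generator makes the correlation authoritative and honors the
interaction ratios only through the cross-year dilution they imply.

**Trial phenotypes.** A plot value is
`mean · (1 + CVg·u + CVe·e + block and main-plot terms)`, where `u` blends
the year-invariant genetic value with a line × year deviate whose relative
variance is set by the G×Y ratios (cross-year genetic correlation ≈ 0.73
for yield, ≈ 0.93 for morphophysiological traits). For yield the deviates
share the MS/PS correlation, so the within-year cross-condition genetic
correlation equals the configured 0.42 in expectation. Per-year means and
CVs are the printed trait summaries. Cereal plot yield responds
phenomenologically (linearly, negatively) to the pea line's MS-yield
genetic value — no crop-growth mechanism. Winter survival and ascochyta
scores are generated only in the first year, whose climate was the only one
producing line variation. Plot values are Gaussian; at the MS yield error
level (CVe 44% around ~1 t/ha) a few percent of plot yields are negative
and are deliberately retained — truncation would bias the second moments
that the recovery studies measure. Validation flags negative yields only
for externally loaded data.

**What the generator does not emulate.** Spatial field trend, missing
plots, selection during RIL development, shared machinery/edge effects,
non-Gaussian yield errors, and linkage between QTL and the population
structure of real founders. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to these
real-data features.

## Problem sizes and runtime choices

Default analyses run the full 144-line design. The recovery study uses 200
replicate single-year datasets with 120 markers (markers only anchor the
QTL part of the architecture there; the estimators operate on phenotypes).
Cross-validation repetitions default to 50 in the analysis scripts and 100
in the formal plan definition; predictive-ability rankings stabilize from a
few dozen repetitions. Realized year-swap gains select only 12 lines, so on
any single synthetic realization they are far noisier than predictive
abilities — across-realization averages are the meaningful quantity.

## Known limitations

* The u test ignores the dependence between correlations sharing genotypes.
* H² and r_g standard errors are delta-method approximations.
* The EM-REML cross-check converges slowly near variance boundaries and
  falls back to the last iterate with a warning.
* BLUPs are one-stage shrunken line means; a full mixed-model BLUP with
  explicit block effects would differ on unbalanced data (which the
  balanced pipeline refuses anyway).
* Bayesian whole-genome regressions (Bayes A/Cπ, Bayesian lasso, RKHS) are
  deliberately out of scope; the ridge model was selected for speed and the
  alternatives differ negligibly for this trait class.
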
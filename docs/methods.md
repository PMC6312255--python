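# Methods

This note documents the statistical model behind each stage of the
pipeline, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Study design assumed

A cohort of n = 29 samples in four lifetime-dose groups — 3 unexposed
controls, 6 low (<100 mGy), 10 medium (100–500 mGy; boundaries inclusive,
matching the interval notation of the binning), 10 high (>500 mGy) — with
per-sample age, BMI, smoking and alcohol covariates. Smoking and alcohol
carry no variation (all exposed workers smoke and drink in the emulated
setting) and are therefore never usable as regressors. Protein abundances
are positive reals with optional missing values; transcript counts exist
for 2 control + 2 high samples only.

## Synthetic cohort generator

The generator is first-class, tested code: its defaults *are* the study
conditions, and a truth table records every planted parameter.

**Covariates.** Doses are uniform within group ranges (control 0, low
U(10, 99), medium U(100, 500), high U(501, 2000) mGy). Age is coupled to
dose through a Gaussian copula: a latent bivariate normal with Pearson
correlation ρ_P = 2 sin(πρ_S/6) chosen to give a target Spearman
ρ_S = 0.7; doses are reordered to follow the ranks of the first latent
coordinate, the second maps to age ~ N(60, 8), clipped to [35, 90] years.
BMI ~ N(27, 3) is independent of both. With n = 29 the realized ρ is
noisy (SD ≈ 0.12) but unbiased; at 10× group sizes it converges to the
target (tested).

**Proteome.** Per protein, on the log scale:
baseline + β_d·dose/1000 + β_a·(age−mean)/10 + β_b·(BMI−mean)/5 + shape
term + N(0, σ) with σ = 0.5 by default. The covariate scalings (per Gy,
per decade, per 5 BMI units) make a single `effect_size` e interpretable
across covariates: β = e·σ moves the mean by about e residual SDs across
the covariate's typical range. Categories (dose-only / age-only / both /
BMI / none / ∪ / ∩) zero the irrelevant coefficients; signs are random.
Gaussian-on-log noise is an assumption of convenience — real label-free
abundances have intensity-dependent variance and informative missingness,
neither of which is modelled (missingness, when enabled, is MCAR only).

**Non-monotone shapes.** ∪/∩ features add a quadratic in the dose-group
rank r ∈ {0..3}, zero at the control and with vertex at r = 1.25:
offsets ≈ (0, +0.96, +0.64, −0.96)·e·σ for ∩ (negated for ∪). The ∩ thus
rises at low/medium doses and falls *below* the control level at high
doses. This choice is deliberate: a quadratic that merely returns to the
control level at high dose produces only positive significant many-to-one
comparisons and is, by the classification rule below, an "up" response —
non-monotonicity only becomes a detectable category when the high-dose
arm crosses the control level.

**Transcriptome.** Counts are gamma-Poisson (negative binomial) with mean
s_j·q_i·fold^{group}: relative expression q_i log-normal (σ_log = 1.6),
library factors s_j ~ U(0.7, 1.3), dispersion α = 0.05 by default, depth
2×10⁶ expected reads/sample. A configurable fraction (default 0.6) of the
genes mapped to dose-only proteins receives the planted fold (default 4)
in the *same direction* as the protein effect; all other genes are null.
The feature map gives ~90% of proteins one gene and a tenth of those a
second gene, exercising the minimum-p gene selection rule.

**Gene sets.** One "planted pathway" set drawn mostly from coherent
planted genes plus uniform random sets over the mapped-gene universe —
structural stand-ins for curated collections, not biological content.

What passing tests on this generator shows: the pipeline's *statistical*
properties (calibration, FDR control, recovery power, superiority of the
integrative route) under the declared noise model. What it does not show:
robustness to normalization artefacts, batch effects, informative
missingness, or real annotation structure.

## Preprocessing

**Dixon screening** uses the two-sided ratio statistic (max of the low-
and high-end gap ratios) with the conventional size staircase: r10 for
n ≤ 7, r11 for 8–10, r21 for 11–13, r22 for n ≥ 14. Critical values are
generated by Monte Carlo (10⁶ Gaussian samples per n, seeded by n, cached
per process) and agree with published two-tailed tables to ~0.01 for
n = 3–10 (tested). At most one value is flagged per call; outliers are
flagged and reported, not removed, unless explicitly requested — the
emulated setting showed no sample with a significant pile-up of outlying
values, so the removal path rarely triggers.

**Box-Cox** is fitted per protein across all samples (not per dose/age
subgroup — with 3-sample groups subgroup-wise transforms are unstable;
this is a documented choice where either reading is defensible). The
profile log-likelihood (λ−1)Σlog y − (n/2)log σ̂²(λ) is evaluated on a
dense grid over [−3, 3] (step 0.01, vectorized) and refined by bounded
search; non-positive inputs are shifted by 1 − min(y), recorded in the
result. λ is only identified when the coefficient of variation is
non-negligible; at CV → 0 the likelihood is flat and the MLE is
arbitrary (harmless: all λ give a nearly affine transform there).

## Dose/age deconvolution

Per protein, OLS of the transformed abundance on standardized dose, age,
dose×age and BMI; AIC = 2k − 2·loglik with k counting intercept, slopes
and residual variance. Backward elimination removes, at each step, the
single term whose deletion lowers AIC most, never removing a main effect
while the interaction is present; ties break by larger coefficient
p-value, then alphabetically. Dose enters as continuous standardized mGy
(not as a group factor): it maximizes power for monotone trends and
matches the "dose-dependent" framing of the categories.

Classification at α = 0.05 on the final model: *dose_age* if the
interaction is significant or both main effects are; *dose_only* /
*age_only* if exactly that main effect is significant; *bmi* if only BMI
is; *none* otherwise. Note that AIC retention and significance are
different events: under pure noise each irrelevant term survives AIC with
probability ≈ P(χ²₁ > 2) ≈ 0.16, so the intercept-only model appears in
only ~half of null fits, but the *category* still lands on "none" in
>80% because retained terms are rarely significant. Proteins that fail
the fitting preconditions (too few complete values, zero range) fall into
"none" as well.

Measured operating characteristics at effect 3σ and ρ(dose, age) ≈ 0.7:
dose-only recovery ≥ 90%, age-only ≥ 80%, both ≥ 95%; with ρ ≈ 0 the
dose-only false-assignment rate for age-only features stays below 2α.

## Group-wise dose response and shape filtration

**Kruskal–Wallis** with tie correction; p from χ²₃ except for total
n ≤ 10 where the exact permutation distribution is enumerated. Rank tests
are invariant under the (monotone) Box-Cox transform, so the transform
matters only for the group means used by the shape contrast.

**Storey q-values** with fixed λ = 0.5 (no smoother): π̂₀ = min(1,
#{p > λ}/(m(1−λ))), q = step-up cumulative minimum of π̂₀·m·p_(j)/j. When
π̂₀ caps at 1 the q-values equal BH exactly (tested as an identity).

**Dunnett** many-to-one comparisons use the pooled-variance t statistics
and the k-variate t distribution with the standard correlation structure,
evaluated by seeded quasi-Monte-Carlo integration (scipy); adjusted
p-values are reproducible for a fixed seed and agree with a brute-force
max-|t| Monte-Carlo oracle within 0.005 (tested), with family-wise error
0.05 ± 0.01 under a 10,000-replicate null.

**Shape rule.** flat if q > FDR level (0.05); else *up* (*down*) if at
least one Dunnett comparison is significant and all significant ones
share the positive (negative) direction; everything else — mixed
directions or no significant post-hoc at all — is non-monotone, subtyped
by the quadratic contrast (1, −1, −1, 1) over the ordered group means:
positive curvature ∪, negative ∩ (a zero contrast, measure-zero in
practice, falls to ∩). Non-monotone features with no significant
post-hoc are included in the shape set by design: the group-wise screen
already established a dose-group effect, and excluding them would leave
such features unclassified.

## Transcript differential expression

Genes with < 15 total counts are discarded (strict less-than). Library
sizes are median-of-ratios factors scaled to geometric mean 1 (identical
up to scaling to the reference implementation in pyDESeq2; tested).
Per-gene dispersions: method-of-moments on normalized counts with group
means removed (2 residual df in the 2-vs-2 design), a robust Huber trend
α(μ) = a₀/μ + a₁ across genes, divided by the Huber location of Exp(1)
(≈ 0.860) — the gene-wise estimates carry multiplicative χ²₂/2 noise, so
an uncorrected robust fit tracks a low quantile and systematically
underestimates α. The final dispersion floors at the trend and shrinks
upward outliers halfway toward it. The floor is essential at this
replication level: allowing gene-wise estimates below the trend (e.g. a
symmetric 50/50 midpoint) lets sampling noise in the variance estimate
inflate the Wald statistics of exactly the genes that then get selected,
and the empirical FDR at BH 0.05 rises to ~0.17 even when the trend is
perfect; with the floor it is ≈ 0.02 at recall ≈ 0.8 (fold 4, default
depth, 50 seeds).

The test itself is a log-link NB GLM per gene (intercept + group
indicator, log size factors as offset), fitted by vectorized IRLS with
working weights μ/(1 + αμ); Wald statistic β/SE against the Gaussian,
two-sided, BH across tested genes. No LFC shrinkage, no outlier
(Cook's) filtering, no independent filtering beyond the count rule —
deliberately minimal, matching what the inputs can support. Non-converged
genes (100 iterations) carry NA p-values.

## Integration

The proteomics side contributes a dedicated two-sided Mann–Whitney U of
high-dose vs control per protein (exact null for combined n ≤ 20),
direction from the difference of group medians. This is the default
rather than the Dunnett high-group p because the integration compares
exactly two groups and a two-group rank test matches the nonparametric
stance of the proteomics screen; the Dunnett-p route is available via
`RunConfig(integration_protein_p="dunnett")`. For proteins with several
mapped, tested genes the minimum-p gene is chosen (ties: lexicographic).
Fisher's statistic −2(ln p₁ + ln p₂) is referred to χ²₄, computed in
closed form e^(−x/2)(1 + x/2) (matches the numeric survival to 1e-10,
tested); exact-zero p-values are clamped to 1e-300 with a warning. One BH
correction across pairs; coherence = share of significant pairs whose
directions agree. The restrictive comparator intersects the layers'
0.05-significant sets and partitions by direction.

## Enrichment

One-sided hypergeometric over-representation per gene set, sets
intersected with the universe first, sets sharing < 2 features with the
universe skipped, BH across tested sets (threshold 0.05 on adjusted p,
configurable). The universe is always the feature list *tested in the
originating stage* — for pair-level enrichment, the genes that actually
entered pairing — never the whole genome: selections are confined to
that universe, and a broader one manufactures spurious enrichment for
any set drawn from it.

## Exploration

Spearman correlation with average ranks (exact permutation p for n ≤ 9,
t approximation otherwise). Sample clustering uses d(i, j) = 1 − ρ_S over
a chosen feature subset and average-linkage agglomeration (complete and
Ward available); the pipeline clusters on the KW-significant dose-only
proteins and reports whether cutting at k = 2 separates controls from
high-dose samples.

## Orchestration and reproducibility

`run_all` executes simulate → deconvolve → dose-response → DE →
integrate → enrich → cluster, writing per-feature TSV reports
(deterministic row/column order, 17-digit floats) and a `summary.json`
with sorted keys. One global seed fans out to per-stage child seeds by
CRC-32 hashing of the stage name, so stages re-run in isolation reproduce
their in-pipeline results; repeated runs are byte-identical (tested).

## Problem sizes used in the checks

The test suite and acceptance script size their simulations to the
package's intended regime: the full 29-sample cohort everywhere; 40–200
proteins and 300–2,000 genes per replicate for the repeated-seed
property checks (50 seeds where a rate is being estimated), and one
cohort-scale run (1,281 proteins, 25,221 genes) in the acceptance
script. Null calibrations use 100,000 pairs (Fisher) and 10,000
replicates (Dunnett family-wise error).

## Known limitations

Dose enters the deconvolution linearly; genuinely non-monotone dose
dependence is handled by the shape stage, not the regression. The NB
stage supports exactly two groups and no covariates. The Dunnett step
requires ≥ 2 non-missing values per group and equal-variance pooling.
P-value combination assumes independent layers; with shared samples the
χ²₄ reference is approximate (the cohort overlap here is 4 samples).
Enrichment is over-representation only, with no rank or topology
information.
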
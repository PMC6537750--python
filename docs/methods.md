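# Methods

This note records the models, defaults and design choices behind
`brainclock`, and what the synthetic-cohort tests do and do not establish
about real data.

## Synthetic cohorts (`synth`)

Expression follows

    x_gi = mu_g + shift_gc + b_g (age_i + delta_i) + w_g' z_i + eps_gi

* `mu_g ~ N(6, 2)`: baseline log-scale abundance; `shift_gc ~ N(0, 0.5)` a
  per-cohort dataset effect (removed downstream by per-cohort
  standardization).
* `b_g`: age slope, zero for non-age genes; magnitudes uniform in
  [0.5, 1.5] × `slope_scale` (default 0.02 expression-units/year), signs
  fixed per gene and shared across cohorts. With `noise_sd = 1` and a
  ~70-year age span this puts per-gene R² in the 0.05–0.2 range typical of
  bulk brain data.
* `delta_i ~ N(0, rate_sd²)`, default `rate_sd = 5` years: the subject's
  aging-rate offset, entering every age gene through the effective age.
  Normality is an assumption — the empirical distribution of aging offsets
  is unknown; ±1 SD then coincides with the ±5-year bins used downstream.
* Nuisance: RIN ~ N(7.5, 1), PMI ~ N(15, 5), sex ~ Bernoulli(0.5), batch
  uniform over 4 levels; each gene receives independent normal loadings
  per covariate (SDs 0.3/0.1/0.2/0.3 expression units). This is the
  simplest structure that makes residualization non-trivial.
* Cohort ages are uniform within configurable ranges; the default design
  (25–97, 25–90, 67–108; n = 250 each) mimics a broad-age training cohort,
  a validation cohort and a much older naturalistic cohort.

Phenotypes: ε4 allele count ~ Binomial(2, 0.14) (the population allele
frequency); AD ~ Bernoulli with
logit p = β₀ + β_Δ δ + β_ε4·carrier + β_int·δ·carrier, defaults
(−1.0, 0.05, 0.8, 0.15/yr) giving ~30% prevalence and a carrier odds ratio
near the epidemiological 2–4×; cognition slope = a₀ + a_Δ δ + noise; 38
null phenotypes are independent standard normals, forming the calibration
panel. Methylation: informative probes are linear in F(age + δ_meth) with
slopes ≤ 0.08 so betas stay inside [0, 1] without clipping up to age ~120;
δ_meth = ρ δ + √(1−ρ²) ε with ρ = 0.7 by default; the generated coefficient
table inverts the construction exactly, so the noise-free clock returns
age + δ_meth identically. Beta values use this clipped linear model rather
than a logit-normal — adequate for clock-application tests, not for
probe-level realism.

What the generator does **not** emulate: count-based (negative binomial)
RNA-seq noise, library-size/composition effects, isoform structure, hidden
confounders, nonlinear age trajectories, and realistic LD/genotype
structure. Tests passing on these cohorts show the chain is correct and
well-calibrated under its own assumptions; they do not certify performance
on real RPKM matrices.

## Preprocessing (`preprocess`)

* Outlier flagging uses leave-in z-scores (gene mean/SD over all samples,
  SD with ddof = 1), threshold 4 — the simplest reading of a ±4 SD rule.
  Leave-in implies |z| ≤ (n−1)/√n, so tiny cohorts (n ≤ 17) can never flag;
  this is documented behavior, not a bug. Zero-variance genes flag nothing.
* Samples whose flagged fraction exceeds `max_outlier_fraction`
  (default 0.05, a choice — "a large number of genes" is not quantified
  anywhere) are dropped before imputation.
* KNN imputation: k = 10, nan-Euclidean distance over co-observed genes,
  unweighted mean of donors that observe the target gene
  (scikit-learn's `KNNImputer` on the transposed matrix). Observed entries
  pass through bit-exact.
* Standardization: per-gene mean 0, SD 1 (ddof = 1); zero-variance genes
  dropped with a warning.
* Residualization: OLS residual on intercept + covariates (categoricals
  indicator-coded); age is never admitted to the design; rank-deficient
  designs raise, naming the collinear columns. Only observed covariates are
  removed — no surrogate-variable estimation.
* The cleaned output is the **rescaled** residual (per-gene SD restored
  to 1). Residualization shrinks each gene's SD by its covariate R², so
  without rescaling a second pass of the pipeline would rescale residuals
  by 1/√(1−R²) and the composite would not be idempotent; with it the
  pipeline is idempotent to machine precision, barring re-flagging of
  borderline Gaussian tails (probability ~6×10⁻⁵ per entry). Unit-variance
  predictors also keep the elastic-net penalty on a single scale.
* Each cohort is preprocessed independently; cross-cohort comparability is
  the recalibration line's job, not the normalizer's. Matrices are assumed
  to arrive on an approximately Gaussian (e.g. log) scale; the 4-SD rule is
  applied to whatever scale is supplied.

## The clock (`clock`)

* Screen: per-gene simple regression of cleaned expression on raw age
  (years); two-sided t-test on the slope (n−2 df); BH step-up q-values;
  selection strictly below q = 0.001, split by slope sign. The screen runs
  on residualized data rather than including covariates per gene — the
  covariates have already been projected out.
* Elastic net in the (α = L1 fraction, λ = overall penalty) convention,
  objective written out in the README; this is the convention under which
  a near-ridge α = 0.01 with a strong λ ≈ 99 on a years-scale target is
  meaningful, and ages are deliberately left in raw years so λ keeps that
  scale. λ = 0 is solved as OLS, α = 0 by closed-form ridge, everything
  else by coordinate descent (tol 1e−8); the solver is validated against a
  generic Powell minimizer of the written objective to 1e−6.
* Tuning maximizes validation-cohort Pearson R over the grid; ties within
  1e−6 prefer larger λ, then larger α (parsimony). Grid points whose model
  predicts a constant (full shrinkage) are skipped. Default grids:
  α ∈ {0.01, 0.1, 0.5, 0.9, 1.0}; λ: 19 points log-spaced 10⁻²–10³
  plus 99.
* Prediction standardizes nothing itself — the target cohort is cleaned
  (hence standardized) internally, and comparability across cohorts is
  restored by recalibration, since mean-normalized datasets cannot share an
  absolute age scale. Panel genes are matched by ID; if >20% of
  nonzero-weight genes are missing the prediction errors out, otherwise
  missing genes contribute the standardized mean (0) with a warning.
* Δ age is the residual from the per-cohort least-squares line of predicted
  on chronological age: Σ Δ = 0 and Σ Δ·age = 0 exactly, per cohort.
  Because strong penalization compresses prediction spread, estimated Δ has
  a smaller SD than the true offset (≈0.9 vs 5 years in the default demo)
  while remaining highly correlated with it (r ≈ 0.86); analyses that bin Δ
  should therefore use ±1 SD bins rather than fixed ±5-year bins.
* The three panel counts (selected up/down, panel size, nonzero weights)
  are reported separately and are not expected to coincide: near-ridge fits
  keep almost every panel gene nonzero, lasso-like fits do not.

## Methylation gauge (`methclock`)

Linear clock: methylation age = F⁻¹(intercept + Σ w_p β_p) with the
piecewise transform F(a) = log(a+1) − log(adult+1) for a ≤ adult (default
adult = 20), (a − adult)/(adult+1) above; F and F⁻¹ are exact inverses to
1e−10 over [0, 110]. Coefficients are user-supplied TSV (probe_id, weight,
optional mean_beta; one `(Intercept)` row) — no published coefficient
values ship with the package. Missing probes: ≥80% of nonzero-weight probes
must be present; absentees are imputed at the training mean beta (or 0.5)
with a warning. Methylation Δ age is the plain difference meth age − chron
age — intentionally *not* residualized, unlike the transcriptional Δ; the
asymmetry is the two definitions' own. A residualized methylation Δ needs
no dedicated flag: `clock.recalibrate_delta` accepts any per-sample age
estimate, including methylation ages, when a symmetric comparison is
wanted.

## Associations (`assoc`)

"Adjusting for" a covariate means including it as a regressor in one
multiple-regression model (not pre-residualizing the outcome). Linear
models report the slope t-test, logistic the Wald test on the log-odds per
unit exposure; `family="auto"` resolves to logistic on exactly two distinct
outcome values. Complete-case analysis with the used n reported. Constant
outcomes raise; separation or non-convergence in logistic fits yields a
flagged row rather than a crash. BH correction runs within each exposure
family across the panel (one family per exposure column), mirroring a
two-column Δ-age / ε4 report. Stratified reruns skip strata with n < 10.
Survivor-effect or sex analyses are expressed as panel specs (e.g.
Δ ~ age within an age > 60 stratum), not special-cased code.

## Synergy (`synergy`)

Bins: younger / neutral / older with boundaries at ±threshold; boundary
values fall in neutral (closed interval, a convention). `fixed` mode uses
±5 years, `sd` mode ±1 SD of the supplied Δ — equivalent when Δ has SD 5,
and `sd` is the right analog for shrunken estimated Δ. Carriers pool 1 and
2 ε4 alleles. Cell odds are cases/(non-cases); the reference is the
whole-cohort odds (the "average odds"); alternative references would be a
one-line change but are not the default since the cohort average is the
natural anchor. Zero-case or zero-control cells get the Haldane–Anscombe
+0.5 correction and a flag; empty cells report NaN. The continuous
logistic interaction test (Wald on the Δ × carrier product) is a
model-based companion to the binned table, labeled as such in outputs;
the binned table itself is unadjusted.

## Markers (`markers`)

Marker lists are inputs (one gene set per cell type); astrocyte +
oligodendrocyte + microglia pool into "glial". Venn partition counts are
exact; the upper-tail hypergeometric p is an addition on top of the
descriptive counts (the qualitative argument needs only the small
fractions). The background is the set of genes tested in the age screen,
not the genome — enrichment against the selection universe, not against an
unrelated reference.

## Pipeline, I/O, determinism (`pipeline`, `io`)

Canonical dialect: TSV, UTF-8, `NA` for missing, first column the
gene/probe ID, header row of sample IDs; duplicate IDs, ragged rows and
non-numeric cells are hard errors with line numbers. Gene IDs are opaque
strings — symbol/Ensembl mapping is upstream of this package. A single
global seed fans out to per-stage seeds via SHA-256 of "seed:stage"
(truncated to 31 bits), so stages are decorrelated but individually
reproducible; identical config + seed reproduce bit-identical outputs and
manifest checksums. The manifest records config hash, package version,
per-stage wall time and SHA-256 of every output.

## Problem sizes

The default demo and the acceptance script use 3 cohorts × 250 subjects ×
2,000 genes (500 age-regulated), 1,000-replicate calibration loops at
n = 200–300, 100-replicate power loops at n = 400, and 20-seed permutation
loops at 1,000 genes × 150 subjects — sizes chosen so the full suite and
the acceptance run each finish in about a minute on one core while keeping
Monte-Carlo error small relative to the tested margins.

## Known limitations

* The clock is linear and assumes the age signature is monotone and shared
  across cohorts; nonlinear trajectories would be absorbed into the
  recalibration line, not modeled.
* Estimated Δ age is attenuated (shrunken SD) relative to the true offset;
  analyses using its magnitude in years should account for that.
* The permutation null holds for the pipeline as trained (screen selects
  ~nothing under permuted ages, leaving a trivial clock); forcing a panel
  despite a null screen leaks true age genes with random weights and can
  produce spurious held-out correlations of |R| ≈ 0.2–0.6.
* The interaction test's power at the documented high-power setting
  (β_int = 0.15/yr, n = 400) is ≈0.78 by direct simulation — adequate but
  not comfortable; studies needing 80%+ power should plan for larger n or
  effect.
* Logistic fits flag separation rather than applying penalized (Firth)
  corrections.
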
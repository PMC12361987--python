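# Methods

This note records the statistical model behind `methdx`, the defaults
and why they were chosen, what the synthetic-cohort generator does and
does not emulate, and the numerical and design decisions a maintainer
should know about.

## Beta calling

The observed methylated fraction at a site is modelled as
`p_obs = β + (1 − β)(1 − e)`: every truly methylated molecule reads
methylated, and a fraction `1 − e` of unmethylated molecules escapes
bisulfite conversion and also reads methylated. Inverting gives
`β = (p_obs − (1 − e)) / e`, clipped to [0, 1]. This is the standard
non-conversion correction; it assumes non-conversion is uniform across
sites and ignores over-conversion of methylated cytosines (typically an
order of magnitude rarer). β is non-decreasing in `e`: a lower
conversion efficiency attributes more of the observed signal to
artifact, and the clip at 0 activates whenever `p_obs` falls below the
non-conversion floor `1 − e`.

The coverage filter is strict (`n_total > min_coverage`, default 30),
so a site covered by exactly 30 reads is missing. Coordinates are
1-based CpG cytosine positions on the forward strand; BED inputs
(0-based half-open) are converted on read. CpG dyads are assumed
pre-collapsed to the forward strand; the package does not merge
strands.

## DMS discovery

Group comparison uses the Wilcoxon rank-sum test because panel beta
values are strongly bimodal (peaks near 0 and 1). The implementation
delegates to `scipy.stats.mannwhitneyu`: exact enumeration when the
pooled sample size is ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. p values are
adjusted with Benjamini–Hochberg over exactly the tested sites.

Two ordering decisions matter:

* **Detection filter before testing.** The ≥ 65 % measured-fraction
  rule is applied per compared group (both groups must qualify — the
  stricter reading; `detect_scope="overall"` gives the pooled-cohort
  alternative), and BH runs only over the surviving sites. Filtering on
  a statistic independent of the test preserves FDR control and
  matches the workflow of detecting sites first, then testing.
* **Threshold boundaries.** The delta cutoff is inclusive (≥), the
  FDR and p cutoffs strict (<); the FDR comparator is configurable
  (`lt`/`le`) because reported subgroup analyses sometimes use ≤.

Delta methylation is the difference of group means over non-missing
entries, unweighted by coverage. Age dichotomisation puts the boundary
age in the younger group (a 55-year-old is "younger" at cutoff 55).
Annotation enrichment is the ratio of category fractions,
`(k/m)/(K/M)`; categories absent from the background are reported as
undefined (NaN), not infinite.

## Stability selection

Candidates are mean-imputed (training means computed once and frozen,
avoiding per-subsample imputation heterogeneity) and standardised. The
penalty convention is mean logistic loss + λ‖w‖₁ with an unpenalised
intercept, so the liblinear `C = 1/(nλ)`; `intercept_scaling=100`
neutralises liblinear's intercept penalty and keeps the analytic
λ_max = max|Xᵀ(y − ȳ)|/n valid (the grid starts 2 % above it for solver
tolerance and spans 4 decades over 100 log-spaced points).

λ is chosen once on the full training set and reused across subsamples
(cost and stability; per-subsample re-selection sits behind
`lambda_per_subsample`). The default rule is "1-se": the largest grid λ
whose mean 10-fold CV binomial deviance is within one standard error
(across folds) of the minimum. `min`, `aic` and `bic` rules are also
implemented; the information criteria penalise the full-fit deviance by
the nonzero-coefficient count plus intercept.

Subsamples are drawn without replacement at fraction 0.8, stratified by
class (stratification guarantees both classes in every subsample, so no
retry loop is needed). 0.8 preserves enough of a ~70-sample training
cohort for the logistic fits to be stable while still perturbing the
data; the fraction is configurable. A coefficient counts as selected
when |β| > 1e-8 after fitting at tolerance 1e-9. The final panel keeps
candidates selected in more than `freq_threshold` of `n_subsamples`
(450/500 by default).

**Known boundary behaviour.** When the candidate set consists of a few
strong, mutually redundant markers (as in the synthetic recovery runs,
where 5–6 markers of delta 0.3 make most training subsamples linearly
separable), the L1 path has no incentive to include the last redundant
marker, and the weakest marker's selection count fluctuates around the
450 threshold across seeds. The selected panel in those runs is always
5–6 of the 6 planted markers with no noise markers, and the validation
AUC is unaffected. This is inherent to LASSO under strong correlated
signal, not a defect of the counting.

## Diagnostic model

The final model is an unpenalised maximum-likelihood logistic
regression on the selected markers plus clinical covariates: age
standardised by training mean/sd, gender encoded F=0/M=1, smoking
never=0/ever=1. Covariates enter only this final fit, not the LASSO
stage. Missing marker betas are imputed with stored training means.

Separation is detected as non-convergence, non-finite standard errors,
or coefficients exceeding 1e3; the model is then refit by Newton IRLS
with an L2 ridge (α = 1e-4 on non-intercept terms) and the results
carry a warning flag. With near-perfect synthetic markers the ridge
path is the norm rather than the exception.

The probability score is the fitted class probability. Classification
uses a configurable threshold, default 0.5, with score ≥ threshold ⇒
malignant (ties positive). Reported displays round sensitivity and
specificity to integer percent and the proportions to three decimals;
full precision is retained internally and in the JSON serialisation.
AUC is computed by midranks (equal to the trapezoidal area under the
empirical ROC and to pair enumeration with ties counted half), and the
train/validation split takes `floor(0.7 n)` training samples uniformly
at random.

## Methylation haplotype load

For a block of L CpGs, every contiguous window of length i = 1…L that
is fully observed within a read (no '.') contributes to `MH_i`, the
fraction of such windows that are all-methylated; windows spanning an
uncovered CpG are excluded entirely, since only fully observed
haplotype substrings are informative. `MHL = Σ i·MH_i / Σ i`, where
lengths with zero observable windows drop out of both sums. Linear
weights emphasise long fully-methylated haplotypes. MHL is computed per
sample (required for per-sample classification), pooling reads within
the block; `min_reads` defaults to 1. For L = 1 the score reduces to
the plain methylation fraction. Blocks are user-supplied BED; the
package does not derive genome-wide blocks.

DMR discovery reuses the DMS machinery on the block × sample MHL
matrix (default: FDR < 0.05 with no delta floor). Nearest-gene
assignment is per chromosome: distance 0 on any overlap, otherwise the
gap between closest interval ends, ties to the smaller gene start, and
regions on chromosomes absent from the gene track are flagged
unassigned.

## Tissue–plasma concordance

Deltas for a fixed (tissue-discovered) site set are computed in each
matrix with the same group-mean convention, then compared by Spearman
correlation (midrank Pearson; two-sided p from the t approximation with
n − 2 df) and classified by sign: concordant if the delta product is
positive, discordant if negative; sites with an exactly zero delta in
either matrix are excluded from both classes, since the two-class
definition is silent on zeros. `mode="paired"` restricts to samples
with a pair id; `mode="whole"` uses every labelled sample.

## Synthetic-cohort generator

What it emulates:

* **Bimodal beta marginal** — site means drawn from an equal-weight
  mixture of Beta(2, 33.33) and Beta(33.33, 2) (modes ≈ 0.03 / 0.97).
* **Planted DMSs** — `n_dms` sites whose class means differ by
  `delta_target`, half hypermethylated and half hypomethylated in
  cases. The base mean is drawn from the mixture component matching the
  direction, truncated so the shifted mean stays inside [0, 1]; a
  delta that cannot fit raises an error rather than clipping.
* **Inter-individual dispersion** — each sample's true level at a site
  is Beta(μκ, (1−μ)κ) around the class mean μ with concentration
  κ = 30 (sd ≈ 0.03–0.08 depending on μ), the magnitude of
  inter-individual variation typical of targeted panels. Without it,
  every planted marker separates the classes perfectly at realistic
  coverage and all fitted models are trivially perfect — not the
  structure a real cohort has. The dispersion is class-independent, so
  all null properties are preserved; κ = 0 disables it.
* **Sequencing** — Poisson coverage (default mean 200×), i.i.d.
  class-independent capture missingness (`detection_rate`, default
  0.9, keeping the 65 % filter unbiased under the null), binomial read
  counts through the conversion channel (default e = 0.99).
* **Plasma dilution** — a case's plasma level is
  `f · (own tissue level) + (1 − f) · background draw` with ctDNA
  fraction `f` (default 0.05, the early-stage regime); controls carry
  background draws. The background profile defaults to the benign-class
  site means, making the expected plasma delta exactly `f` times the
  tissue delta — the linear mixture is a modelling choice; no
  tissue-plasma noise model beyond the ctDNA-fraction argument is
  established.
* **Read haplotypes** — reads cover contiguous CpG windows of a block;
  `coordination="full"` sets all covered CpGs jointly (one Bernoulli
  per read), `"independent"` draws per CpG.
* **Covariates** — age, gender, smoking drawn independently of class
  by default; optional class-linked smoking probability and age shift
  for confounding experiments.
* **Annotation fixtures** — category tracks with largest-remainder
  integer allocation (deterministic counts), non-overlapping gene
  intervals, and 4-CpG blocks partitioning the panel.

What it does not emulate: fragment-level effects (no FASTQ, alignment,
fragment-length or end-motif structure), correlated methylation between
neighbouring sites outside haplotype blocks, batch effects, tumor
purity variation within the tissue arm, and cell-type deconvolution of
plasma background. Passing recovery tests therefore demonstrates the
correctness of the statistical machinery under the generator's
assumptions, not clinical performance on real cohorts.

Defaults mirror the target study geometry: 56 cases / 44 controls
(tissue-cohort scale), 2 000 panel CpGs (a desk-scale stand-in for a
~2 × 10⁵-site panel), 6 planted markers of delta 0.3.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which every statistical property is
well-resolved: end-to-end runs use 100 samples × 2 000 sites with 500
stability subsamples (~4 s); the null FDR study uses 100 replicates of
500 sites × 70 samples (~35 s); oracle-equivalence sweeps stay at the
enumerable sizes (rank-sum n ≤ 12, Spearman n ≤ 7, AUC n ≤ 50, MHL
L ≤ 6).

## Reproducibility

Every stochastic component takes an explicit seed. The pipeline derives
per-stage seeds by SHA-256 hashing of (master seed, stage name),
giving independent yet reproducible streams below 2³¹; identical
configs produce byte-identical report bundles, and the run log records
the config hash, stage seeds, and the site/sample counts surviving each
filter.
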
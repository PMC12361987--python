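# methdx

Targeted bisulfite-sequencing methylation diagnostics: from per-CpG
methylation counts to a validated case/control classifier, with
methylation-haplotype scoring and tissue–plasma concordance analysis.

`methdx` is aimed at groups analysing capture-panel bisulfite data from
a two-arm clinical cohort (e.g. malignant vs benign lesions, tumor
tissue and matched plasma cell-free DNA). It implements the complete
marker-discovery workflow as a tested, reusable library plus a CLI, and
ships a synthetic-cohort generator with known ground truth so every
stage can be exercised and validated without patient data.

## The analysis

**Beta calling.** Per-site counts of methylated (`M`) and unmethylated
(`U`) reads give the observed methylated fraction
`p_obs = M / (M + U)`. With bisulfite conversion efficiency `e`, a
fraction `1 − e` of unmethylated cytosines escapes conversion and reads
as methylated, so the methylation level is estimated as

```
β = clip( (p_obs − (1 − e)) / e , 0, 1 )
```

restricted to high-confidence sites (coverage > 30×).

**Differential methylation (DMS).** Per CpG site, case and control
samples are compared with the Wilcoxon rank-sum test (beta values are
bimodal, not normal), with Benjamini–Hochberg FDR over the sites that
are measured in ≥ 65 % of each group. Sites pass on FDR (< 0.05 for
tissue; FDR < 0.2 and p < 0.001 for plasma), absolute delta methylation
(mean(case β) − mean(control β); ≥ 0.15 tissue, ≥ 0.02 plasma), and the
detection rule.

**Stability selection.** The DMS candidates enter an L1-penalised
logistic regression whose penalty λ is the 10-fold cross-validated
"1-se" choice (largest λ within one standard error of the minimum CV
binomial deviance). The training cohort is subsampled without
replacement 500 times (80 %, stratified); a candidate is kept in the
panel when its coefficient is nonzero in more than 450 subsamples.

**Diagnostic model.** The selected markers, plus age, gender and
smoking status, enter an unpenalised logistic regression (ridge
fallback on separation). Each sample receives a probability score
`σ(β₀ + Σ βⱼ xⱼ) ∈ [0, 1]`; score ≥ 0.5 predicts malignant. Performance
is reported as sensitivity, specificity, PPV, NPV, accuracy and the
midrank AUC on both the 70 % training and 30 % validation split.

**Methylation haplotype load (MHL).** For a haplotype block of L CpGs,
reads reduce to patterns over {1, 0, ·}. With `MH_i` the fraction of
fully observed contiguous i-CpG windows that are all-methylated,

```
MHL = Σᵢ i · MHᵢ / Σᵢ i ,   i = 1 … L
```

giving a block-level, co-methylation-aware score in [0, 1]; block ×
sample MHL matrices feed the same rank-sum/FDR machinery to find
differentially methylated regions, which are assigned to nearest genes.

**Tissue–plasma concordance.** Because only a few percent of plasma
cell-free DNA derives from the tumor, plasma effect sizes are a diluted
image of tissue effects. Tissue-discovered DMSs are followed into
plasma via Spearman correlation of the paired per-site deltas and a
sign-based concordant/discordant classification.

**Synthetic cohorts.** The generator plants DMSs of a chosen delta in a
bimodal Beta-mixture background, adds inter-individual dispersion,
Poisson coverage, capture missingness, the bisulfite conversion
channel, and models plasma as the mixture
`f · tumor β + (1 − f) · background β` at a configurable ctDNA fraction
`f`. Every run returns the ground truth for recovery testing.

## Worked example

Run the full discovery pipeline on a seeded synthetic tissue-like
cohort (100 samples, 2 000 panel CpGs, 6 planted markers of delta 0.3):

```python
from methdx.pipeline import RunConfig, run_discovery_pipeline

report = run_discovery_pipeline(RunConfig(outdir="run1", seed=7))
print(report["train_n"], report["validation_n"])      # 70 30
print(report["n_dms_discovered"])                     # 6
print(report["n_markers_selected"])                   # 6
print(report["validation"]["metrics"])
```

prints

```
70 30
6
6
{'sensitivity_pct': 100, 'specificity_pct': 100, 'ppv': 1.0, 'npv': 1.0,
 'accuracy': 1.0, 'auc': 1.0}
```

The cohort split is 70 training / 30 validation samples; all six
planted markers are rediscovered as DMSs, survive stability selection,
and the resulting 6-marker logistic model classifies the held-out
validation samples perfectly (synthetic tissue signal at delta 0.3 is
strong; the plasma dilution of the same cohort at a 5 % ctDNA fraction
drops the validation AUC to ≈ 0.73). The report bundle under `run1/`
contains the DMS table, selection counts, model JSON, per-cohort
metrics and ROC points.

The same stages are available as subcommands:

```
methdx simulate --seed 7 --outdir sim/
methdx call --coverage-dir sim/coverage --metadata sim/metadata.tsv --out matrix.tsv
methdx dms  --matrix matrix.tsv --metadata sim/metadata.tsv --out dms.tsv
methdx run  --config pipeline.yaml
```

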
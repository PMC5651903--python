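# perksig

Tools for asking a recurring question in cancer transcriptomics: *which part
of a stress-signaling pathway is specifically activated in tumors, and does
that activation predict outcome?* The package takes a pathway gene list and
a tumor-vs-normal expression matrix, derives the cancer-specific subset of
the pathway, scores and stratifies patients by it, links strata to
metastasis-free survival, tests which hallmark programs and transcription
factor binding events travel with the signature, and calibrates luminescence
spike-in curves for circulating-tumor-cell (CTC) counting. It was built
around the PERK/CREB3L1 axis in breast cancer but every stage is generic.

## What it computes

**Signature derivation.** Per gene, fold change as the difference of mean
`log2(x + 1)` between tumors and normals and a two-sided equal-variance
Student *t*-test; signature members satisfy `log2FC >= 1` (twofold) and
`p <= α/m` (Bonferroni, α = 0.05, *m* tested genes).

**Scoring and stratification.** Sample score = mean `log2(x + 1)` over
signature genes; strata by descending rank: top/bottom tertiles
(`⌊N/3⌋` each), top half (`⌊N/2⌋`), or top/bottom 33% with the middle third
unassigned, plus a nested two-signature 3×3 binning.

**Survival.** From-scratch Kaplan–Meier, the two-group log-rank test
(`(O−E)²/V`, χ² on 1 df), and the Mantel–Haenszel hazard ratio
`HR = (O₁/E₁)/(O₂/E₂)` with `SE(log HR) = √(1/E₁ + 1/E₂)`, with optional
restriction of follow-up to 120 months.

**Enrichment.** Weighted-KS GSEA (signal-to-noise ranking, ES from the
running sum, NES and FDR from phenotype permutations) and the exact
hypergeometric over-representation test.

**ChIP binding.** Closest-gene peak annotation (summit-or-midpoint anchor),
an exact binomial test of signature binding against the background bound
rate, and half-open interval co-localization with a second mark (e.g.
H3K27ac).

**CTC calibration.** OLS standard curve of luminescence on spiked cell
counts and inversion of readings to cells per ml of blood.

Because the original cohorts are external downloads, the package ships
synthetic-data generators (`perksig.simulate`) that reproduce each study
design — 388 pathway genes across 1093 tumors and 112 normals, 182-subject
survival arms with a true HR of 1.8, a planted EMT-like hallmark set, a
14-of-23 bound signature with 12/14 acetyl co-localization, and the
five-point spike-in series — with planted ground truth, so every stage is
verified by parameter recovery. See `docs/methods.md` for models,
assumptions, and limitations.

## Worked example

```python
from perksig.simulate import (ExpressionScenario, SurvivalScenario,
                              gen_expression_study, gen_survival_cohort)
from perksig.signature import (differential_expression, derive_signature,
                               bin_by_score)
from perksig.survival import restrict_followup, logrank_test, hazard_ratio

study, truth = gen_expression_study(ExpressionScenario(seed=1))
sig = derive_signature(differential_expression(study))
print(f"signature: {len(sig)} of {study.n_genes} genes; "
      f"recovered planted set: {set(sig.genes) == set(truth['planted_genes'])}")

table, scores, _ = gen_survival_cohort(SurvivalScenario(seed=1))
strata = bin_by_score(scores, scheme="tertile")
restricted = restrict_followup(table, 120)
hr = hazard_ratio(restricted, strata)
lr = logrank_test(restricted, strata)
print(f"arms: high n={len(strata.samples_in('high'))}, "
      f"low n={len(strata.samples_in('low'))}")
print(f"HR (high vs low) = {hr.hr:.2f}  [95% CI {hr.ci_low:.2f}-{hr.ci_high:.2f}]")
print(f"log-rank chi2 = {lr.statistic:.1f}, p = {lr.p:.2e}")
```

prints

```
signature: 23 of 388 genes; recovered planted set: True
arms: high n=182, low n=182
HR (high vs low) = 1.82  [95% CI 1.41-2.34]
log-rank chi2 = 21.9, p = 2.87e-06
```

i.e. the twofold + Bonferroni filter pulls out exactly the 23 planted
cancer-specific genes, and the top signature tertile carries an ~1.8-fold
hazard of metastasis over ten years relative to the bottom tertile — the
effect size the cohort was generated with.

The same stages are available from the shell:

```sh
perksig simulate --scenario C1 --seed 1 --out chip/
perksig chip-enrich --tf-peaks chip/tf_peaks.narrowPeak \
    --acetyl-peaks chip/h3k27ac_peaks.bed --loci chip/loci.tsv \
    --signature chip/signature.gmt --out chip/summary.json
```

and `perksig run --config run.yaml --out run/` drives the whole pipeline
from a YAML config, writing a checksummed `manifest.json` for bit-identical
reruns. Subcommands: `simulate`, `derive-signature`, `score`, `stratify`,
`km`, `gsea`, `hyper`, `chip-enrich`, `ctc-calibrate`, `run`.

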
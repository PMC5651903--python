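# Methods

`perksig` implements the downstream computational arc of a tumor-signature
study: derive a cancer-specific subset of a pathway gene list from
tumor-vs-normal expression, score and stratify patients by that signature,
relate strata to time-to-event outcomes, test gene-set and transcription
factor binding enrichment, and calibrate a luminescence spike-in curve for
circulating-tumor-cell (CTC) counting. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Signature derivation

Expression enters on linear scale and is transformed to `log2(x + c)` with
pseudocount `c = 1` (exposed as a parameter; only the presence of a
pseudocount, not its value, is dictated by the upstream convention). For
each gene the fold change is the *difference of group means of the logged
values* — not the log of the ratio of means — and significance comes from a
two-sided equal-variance Student t-test (Welch available behind a flag). A
gene joins the signature when

```
log2fc >= 1        (twofold over-expression)
p <= alpha / m     (Bonferroni, alpha = 0.05, m = genes tested)
```

Genes flat across every sample of both groups get `t = 0, p = 1` and are
flagged. The filter is monotone in both thresholds, and provenance
(thresholds, test count, pseudocount) is stored on the signature object.

Sample scores are the mean of `log2(x + c)` over signature genes. Strata are
rank-based with ties broken by ascending sample id for reproducibility:
top/bottom tertiles (`floor(N/3)` each, so 547 subjects give the 182-per-arm
design), top half (`floor(N/2)`, so 1093 tumors give 546 high), and a
top/bottom-33% scheme that leaves the middle third unassigned. Nested
binning applies the 33% scheme twice — the inner binning uses only
within-bin ranks — yielding four cells (high_high … low_low).

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test, and the
Mantel–Haenszel hazard ratio are implemented from first principles and
cross-checked against `lifelines` in the test suite (agreement to 1e-8 on
survival, 1e-6 on p). Conventions: subjects censored at an event time remain
at risk for that event; times are months; metastasis-style analyses restrict
follow-up to a 120-month horizon by administrative censoring (configurable).
The hazard ratio is the O/E ratio `(O1/E1)/(O2/E2)` with log-scale standard
error `sqrt(1/E1 + 1/E2)` — closed-form, and at the effect sizes of interest
indistinguishable from a Cox fit, which is available via `method="cox"`
(Newton–Raphson on the binary-covariate partial likelihood, Breslow ties).
The choice of the O/E estimator over Cox as the default reflects that the
reproduced survival tool reports KM-derived quantities without specifying an
estimator; the difference is documented rather than hidden.

## Gene-set enrichment

The ranking metric is signal-to-noise `(mu_hi - mu_lo)/(sd_hi + sd_lo + 1e-8)`
on `log2(x + 1)` values with sample standard deviations and no sd floor
(floors are a desktop-tool legacy; the guard epsilon handles zero
denominators). The enrichment score is the canonical weighted-KS running
sum: hits add `|metric|^w / sum_hits |metric|^w` (w = 1), misses subtract
`1/(N - N_hits)`; ES is the signed maximum deviation, clipped into [-1, 1]
against last-ulp accumulation overshoot. The null distribution uses
phenotype (label) permutations by default, switching to gene-set resampling
with a warning when either group has fewer than 7 samples. NES divides ES by
the mean magnitude of same-sign null scores; the nominal p is the same-sign
null tail fraction; FDR q is the classic pooled-NES ratio of null to
observed tail fractions, computed per sign and clipped to [0, 1]. Set-size
filters default to [15, 500] after intersection with the study genes.
Results are deterministic given the seed. Agreement with an independent
GSEA implementation (`gseapy` prerank) is enforced in tests at Spearman
>= 0.9 on NES; in practice it exceeds 0.99.

The over-representation test is the exact hypergeometric upper tail
`P(X >= k)`; annotation-term genes outside the declared universe are dropped
with a warning, a query outside the universe is an error.

## ChIP binding enrichment

Peaks are anchored at the narrowPeak summit when present, else the interval
midpoint, and annotated to the gene with the minimal |anchor - TSS| on the
same chromosome (exact distance ties go to the lower TSS coordinate; both
behaviors are deterministic). "Bound" genes are those that are the closest
gene of at least one peak, optionally within a distance cap — no cap by
default, matching plain closest-gene semantics. Enrichment of binding at a
signature is an exact one-sided binomial test of `k` bound out of `n`
signature genes against a background rate `p0`, which by default is the
bound fraction among non-signature genes of the supplied locus universe
(overridable). Co-localization between two peak sets counts a peak as
overlapping when it shares at least one base under 0-based half-open
semantics.

## CTC calibration

Classical calibration: ordinary least squares of luminescence on the known
spiked cell counts (five design points: 1000, 333, 111, 37, 12 cells in a
0.4 ml blood sample), then algebraic inversion of new readings,
`cells = (reading - intercept)/slope`, normalized to cells per ml. The
intercept is free by default (a zero-intercept fit is a flag) because blank
blood carries background luminescence; readings below the intercept clamp
to zero cells with a flag rather than erroring. No variance weighting is
applied.

## Synthetic scenarios and what they do (and do not) show

Each generator is a pure function of its config (seed included) and plants
ground truth that the corresponding analysis must recover:

* **S-CSPS** — 388 genes x (1093 tumors + 112 normals). Per gene a baseline
  log2 level ~ Uniform(3, 8), per sample Normal noise of sd 1 on log2 scale,
  linear values `max(0, 2^z - 1)`; 23 genes get +2 log2 in tumors only. The
  derivation filter recovers exactly those 23 under every tested seed.
* **M1** — 547 subjects (tertile arms of exactly 182); standard-normal
  scores; exponential event times at 0.0076/month in the bottom score
  tertile, scaled by sqrt(1.8) and 1.8 in the middle and top tertiles (true
  top-vs-bottom hazard ratio 1.8; ~60% bottom-arm event probability by 120
  months); administrative censoring at 120 months and no other dropout. The
  base rate was chosen so that a ten-year window retains both events and
  censorings in every arm.
* **G1** — 5000 genes x (273 + 273 samples); 50 disjoint sets of 100 genes;
  the planted set ("EMT") is shifted +1 log2 in the high group.
* **C1** — one 100 Mb chromosome, 20,000 uniform TSSs; 400 bp TF peaks
  centered within ±500 bp of the TSS at 14 of 23 designated signature genes
  and at Bernoulli(0.2) of background genes (the background rate is a knob,
  not an estimate of any genome); H3K27ac peaks directly overlap the TF peak
  at exactly 12 of the 14. Signature genes are drawn only from loci isolated
  by > 2 kb on both sides so the planted peak provably annotates to the
  planted gene and stray background acetyl peaks cannot brush the two
  deliberately non-acetylated signature peaks; background loci are untouched.
* **SPIKE** — luminescence `(500 + 150·count) · exp(N(0, 0.05))` at the five
  design counts.

The generators emulate effect structure, not real-data pathology: no
RNA-seq count noise (negative binomial), no batch or cohort heterogeneity,
no probe-level microarray artifacts, no correlated genes, and exponential
(constant-hazard) event times. Passing recovery tests therefore
demonstrates correctness of the analysis machinery under its stated
assumptions — not robustness to the messiness of public cohort data.
Effect magnitudes beyond the printed design numbers (noise sd, baseline
range, the +2 and +1 shifts, the 0.2 background binding rate, spike-in
noise) are free parameters chosen once as plausible values for these data
types.

## Numerical choices and degenerate inputs

* Ranking/stratification ties break by ascending identifier everywhere.
* Zero-variance genes: t-test → flagged `t=0, p=1` when means agree
  (p = 0 when they differ); ranking metric → 0.
* Log-rank with no events (or zero variance) returns statistic 0, p = 1
  with a warning instead of dividing by zero; a hazard ratio with a
  zero-event group is an error.
* Binomial background rates of exactly 0 or 1 are rejected with guidance to
  supply an explicit `p0`.
* GSEA nominal p is the plain tail fraction (0 attainable only in the limit;
  q-values are clipped into [0, 1] and nan NES maps to q = 1).
* All interval handling is 0-based half-open; BED/narrowPeak round-trip
  byte-identically with no coordinate shifting.

## Problem sizes used in the checked results

The shipped checks run the full printed design sizes for the expression,
GSEA, and ChIP scenarios; survival calibration uses 200 independent cohorts
(and 1000 for type-I error), GSEA recovery 20 draws, and oracle comparisons
use exhaustive small instances (lists of 8 genes, ≤ 200 peaks/loci) where
enumeration is exact.

## Known limitations

* The reproduced survival tool's exact estimator and probe handling are
  unknown; the O/E hazard ratio is a documented stand-in validated on
  synthetic cohorts.
* Multi-probe collapsing, cross-cohort normalization, and GO ontology
  structure are out of scope; annotation is whatever GMT is supplied.
* Phenotype permutation recomputes the ranking metric per permutation under
  the fixed observed gene ordering cost; extremely small studies fall back
  to gene-set permutation, whose null is known to be anti-conservative for
  correlated sets.
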
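# fgfr-atlas

A pan-cancer expression-biomarker pipeline for the FGF/FGFR axis, written for
translational bioinformaticians who need to ask, cohort by cohort: is a gene
dysregulated in tumors, does its expression stratify overall survival, does it
track drug response in cell lines, and — the headline question — what fraction
of patients would screen biomarker-positive in a trial?

It operates on TCGA-style inputs (a gene-by-sample matrix of linear-scale
RSEM-like abundances plus a sample annotation table) and GDSC-style cell-line
panels (expression, per-line log-IC50 for one drug, binary mutation markers),
and ships a synthetic-data module that generates both with *known planted
effects*, so every stage is testable against ground truth.

## The four stages

**Differential expression.** Per gene *g* and cohort *c* with tumor values
*x* and normal values *y*: the two-sided Wilcoxon rank-sum test (or the
signed-rank test on matched pairs), plus the fold change
log2((mean(x)+1)/(mean(y)+1)). Raw p-values are tiered (P < 0.05,
P < 0.001); a Benjamini-Hochberg column is emitted alongside. Cohorts
without normal tissue are skipped with an explicit reason.

**Survival association.** Tumors with complete (time, event, expression)
triples and ≥ 30 days of follow-up are dichotomized at the cutoff *c**
maximizing the two-group log-rank statistic over all observed expression
values (a maximally selected rank statistic, with each side holding ≥ 10% of
subjects). The high (≥ *c**) vs low contrast is then summarized by
Kaplan-Meier curves, the log-rank test, and a univariate Cox model
h(t|high) = h₀(t)·exp(β), HR = e^β with a 95% Wald CI. Because *c** is
chosen to maximize separation the naive log-rank p is anticonservative; an
optional covariate-permutation p corrects for the selection.

**Drug sensitivity.** Pearson correlation of log2(expression+1) with
log-IC50, pan-tissue and per tissue (≥ 10 lines); two-group one-way ANOVA of
log-IC50 by mutation status, with markers called *sensitizing* (effect < 0)
or *resistance* only under the dual gate raw P < 10⁻³ **and** BH FDR ≤ 25%.

**Positivity prediction.** A trial screening bladder-cancer patients by
RNA-ISH reported 42% FGFR1-or-FGFR3 positives. Assuming ISH positivity is
monotone in RNA-Seq abundance, the cutoff *t* is calibrated so that 42% of
the reference cohort's tumors have max(FGFR1, FGFR3) ≥ *t* — *t* is the k-th
largest observed score with k = round(0.42·n) — and the same *t* then
predicts per-gene and gene-set positive ratios in every other cohort, with
an optional bootstrap CI.

## Worked example

`examples/05_positivity_calibration.py` builds a three-cohort synthetic
atlas (a 407-tumor reference cohort, a cohort expressing every FGFR gene
higher, and a neutral cohort), calibrates the cutoff and predicts ratios:

```
calibrated cutoff = 3975 (linear expression units)
achieved reference ratio = 0.4201
  BLCA (n=407): FGFR1/3 set ratio = 42% [38%, 47%]  |  FGFR1=21% FGFR2=26% FGFR3=28% FGFR4=29%
  CHOL (n=36): FGFR1/3 set ratio = 86% [72%, 96%]  |  FGFR1=69% FGFR2=75% FGFR3=61% FGFR4=64%
  LUSC (n=100): FGFR1/3 set ratio = 47% [37%, 57%]  |  FGFR1=26% FGFR2=31% FGFR3=30% FGFR4=32%
```

The reference cohort reproduces the 42% screening prevalence by construction
(0.4201 = 171/407, within one sample of the target); the brackets are 95%
bootstrap CIs; the planted high-expression cohort shows a clearly higher
predicted ratio, the ordering the method is designed to surface. The other
examples (`examples/01`–`04`) walk through simulation, differential
expression, cutpoint survival analysis and drug-sensitivity association the
same way.

Every stage is also a CLI subcommand (`fgfr-atlas simulate | diffexpr |
survival | drugsens | positivity | run-all`); `run-all` executes the whole
pipeline from a JSON config and writes per-stage TSVs, JSON metadata
sidecars and a digest manifest, fully deterministic under a fixed seed.

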
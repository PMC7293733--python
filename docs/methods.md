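# Methods

## Data model

Expression is a dense gene-by-sample grid of non-negative, finite values on
the **linear** RSEM-like scale. The linear scale is the package-wide
exchange format because the positivity cutoff is defined on it; each stage
applies its own transform (log2(x+1) before correlation; none before rank
tests, which are invariant to monotone transforms; none for fold changes,
which are computed on means of linear values). A gene absent from the matrix
is a hard error, never an NA: the intended inputs are dense. Sample IDs are
matched exactly — no barcode truncation or case folding; normalizing TCGA
barcodes is the caller's job.

Annotations carry cohort code, tumor/normal status, an optional matched-pair
ID (exactly one tumor and one normal per pair), and optional overall-survival
fields (days + event/censored, present together or not at all; encoded 1/0 on
disk).

## Differential expression

Two-sided Wilcoxon rank-sum per (gene, cohort), with midranks for ties.
Exact enumeration is used when both groups have ≤ 25 values and the pooled
data is tie-free; otherwise the normal approximation with tie-corrected
variance and continuity correction (the two branches agree within 0.01
absolute p for tie-free groups of 12–20, checked by sweep in the tests). A
pooled sample with all values identical is degenerate: p = 1 with a flag.
The matched-pair mode runs the signed-rank test on tumor−normal differences,
dropping zero differences first.

The fold-change estimator is log2((mean(x)+1)/(mean(y)+1)) on linear values
— means, not medians, with pseudocount 1, so rarely expressed genes with
zero-heavy groups stay finite and a zero/zero comparison is exactly 0.

Tiers follow raw p (P < 0.05, P < 0.001); no multiplicity correction drives
the tiers, but a BH-adjusted column is always emitted next to them so a
reader can apply a stricter rule. `min_normals` defaults to 1: pan-cancer
atlases legitimately retain cohorts with a single normal sample, and cohorts
below the threshold are reported as skipped with a reason rather than
silently dropped.

## Survival

Inclusion: tumors with complete (time, event, covariate) triples — the
operational reading of "fully characterized" — and follow-up ≥ 30 days
(inclusive), regardless of event status.

The cutpoint is the maximally selected log-rank statistic: every distinct
observed covariate value is a candidate threshold (low < c ≤ high), a
candidate is admissible when each side keeps ≥ `min_prop` (default 0.1, the
conventional default of the maximally-selected-rank literature) of subjects,
and the admissible candidate maximizing the two-group log-rank chi-square
wins, ties breaking toward the smaller cutoff. The scan uses an internal
O(n log n)-per-candidate log-rank with hypergeometric variance (cross-checked
against lifelines in the tests); exhaustiveness is verified against a
brute-force maximizer.

The log-rank p at the selected cutoff is **anticonservative by
construction** and is labeled as such in the output. A covariate-permutation
p (permute expression against (time, event), redo the full search, add-one
correction) is emitted as an extra column when `permutation_reps > 0`; the
standalone `cutpoint_permutation_p` defaults to 1000 replicates. Permutation
is opt-in in the scan because it costs O(n² · reps) per cell.

Cox fits use the partial likelihood with Efron tie handling (Newton-Raphson,
via lifelines), Wald 95% CI, HR = exp(β) for high (≥ cutoff, the same
inclusive convention as positivity) vs low. If one group carries no events
the likelihood is monotone; the fit returns a signed infinite-HR sentinel
flagged non-convergent instead of a spurious finite estimate. Direction is
*adverse* iff HR > 1. Kaplan-Meier curves come from the product-limit
estimator with per-step risk-set counts.

No multiplicity correction is applied across the survival grid by default.

## Drug sensitivity

IC50 is consumed on the natural-log scale (the GDSC convention); expression
is log2(x+1)-transformed before Pearson correlation so a handful of extreme
expressers cannot dominate r. Per-tissue correlations require ≥ 10 lines.
Correlation p-values are reported raw. Marker tests are two-group one-way
ANOVA of log-IC50 (identical to the squared pooled-variance t); BH is applied
within the scanned marker family only, and a marker is called only under
raw P < 10⁻³ AND FDR ≤ 25%, the effect sign deciding sensitizing vs
resistance. Groups with fewer than 2 lines are flagged not-computable.

## Positivity

A sample's gene-set score is the **maximum** linear expression over the set:
"FGFR1 or FGFR3 positive" is union positivity, the only reading consistent
with a single shared cutoff. Calibration takes the reference cohort's tumor
scores s(1) ≥ … ≥ s(n), sets k = round(p·n) (half away from zero) and
returns cutoff = s(k), so the cutoff is always an observed expression value
— distribution-free and exactly reproducible. Positivity is inclusive
(score ≥ cutoff), which makes the calibrated count exact for distinct
scores; a tie block at s(k) can only raise the achieved ratio, which is
reported, never hidden. k = 0 or k = n is an error (the target prevalence is
unattainable at that cohort size). Only tumor samples participate anywhere
in this module. Per-gene ratios for the report genes reuse the same single
calibrated cutoff; the output metadata records this assumption. The optional
CI is a seeded percentile bootstrap over tumor samples.

Guaranteed invariants (all property-tested): ratios are monotone
non-increasing in the cutoff; the set ratio lies between the max and the sum
of member-gene ratios; jointly rescaling expression and cutoff by any c > 0
changes nothing; enlarging the gene set never decreases a ratio; recomputing
the reference ratio at the calibrated cutoff returns the achieved ratio
exactly.

## Synthetic data

The generators exist to give every stage a test bed with known truth, not to
mimic real tumor transcriptomes.

* Expression is log2-normal (per-gene base mean and SD, default mean 10, SD
  1.5 on the log2 scale) exponentiated to the linear scale; tumor means are
  shifted by the planted log2 fold change. The default gene panel is the
  human FGF ligand family (FGF1–FGF14, FGF16–FGF23) plus FGFR1–4.
* Matched pairs share a latent per-pair log2 intercept (SD 0.5 by default,
  shared across genes, like a library-size effect), giving the paired test a
  realistic within-pair correlation to exploit.
* Survival is exponential under proportional hazards:
  h_i = h₀·exp(β·z_i) with z the standardized log2 expression of the linked
  gene, h₀ defaulting to 1/500 events per day. Censoring is an independent
  exponential — matching the Cox model's non-informative-censoring
  assumption — whose rate is solved numerically (Brent) so the expected
  censored fraction equals `censor_rate` (default 0.3); `censor_rate = 1` is
  treated as administrative censoring at the drawn times. Times are rounded
  up to whole days, minimum 1.
* Cell-line log-IC50 = α + β·z(log2 expr) + Σ δ·marker + N(0, σ), markers
  Bernoulli; tissue labels are drawn from the configured mix.

Everything is reproducible from the integer seed; the pipeline fans a single
global seed out to per-stage child seeds via a SHA-256 stage-name hash, so
adding a stage never shifts another stage's stream.

What the simulation deliberately lacks: empirical per-gene distributions,
batch and purity effects, gene-gene correlation beyond the pair intercept,
non-proportional hazards, informative censoring, dose-response curve noise.
Passing tests therefore demonstrate the *procedures* are correct and
calibrated under their stated assumptions, not that real cohorts satisfy
those assumptions.

## Problem sizes and numerical choices

The test suite validates null calibration on 1000-cell grids (20 cohorts ×
50 genes at n = 30+15; 1000 genes × 100 cell lines) and parameter recovery
at n in [200, 500] with fixed seeds — sizes chosen to put Monte-Carlo error
well inside the asserted tolerances while keeping the whole suite fast. The
planted-fold-change fixture uses a per-gene log2 SD of 0.5, a realistic
within-cohort spread for a moderately expressed gene, giving the fold-change
estimator a standard error comfortably inside the ±0.3 recovery band at
n = 50+20. Cutpoint ties break toward the smaller cutoff; chi-square
comparisons use a 1e-12 slack; the exact-test threshold (25 per group) keeps
exact enumeration affordable.

## Integration note (external data)

Run against the real TCGA legacy RSEM matrices with the bladder-cancer
reference and a 42% target, the calibration should land near the published
cutoff of 4,220 with cholangiocarcinoma showing the highest FGFR1/3 union
ratio. That check requires the external download and is documented here as
an integration check; it is not part of the test suite.

## Known limitations

* Optimal-cutpoint survival p-values are reported as the field reports them
  (uncorrected) — the permutation column is the honest version; use it.
* The Cox stage is univariate only: no covariate adjustment, time-varying
  effects or competing risks.
* The drug stage does not refit dose-response curves and uses plain
  two-group ANOVA, not a covariate-adjusted MANOVA.
* Calibration transfers a screening prevalence across assay technologies
  under a monotonicity assumption that cannot be verified from expression
  data alone.
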
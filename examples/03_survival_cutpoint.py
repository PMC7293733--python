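"""Optimal-cutpoint survival association for one gene in one cohort.

Tumors carry a planted hazard ratio of e^0.7 ~ 2 per SD of log2 FGFR1
expression.  The scan dichotomizes expression at the cutoff maximizing the
log-rank statistic, then reports the log-rank test and the univariate Cox
hazard ratio of high vs low expressers.  Because the cutoff is selected to
maximize separation, the naive log-rank p is anticonservative; the
permutation-adjusted p corrects for that selection.
"""

import fgfr_atlas as fa

matrix, annots = fa.generate_cohort(
    fa.CohortSpec("BLCA", n_tumor=200, n_normal=0,
                  survival_link=fa.SurvivalLink("FGFR1", 0.7),
                  censor_rate=0.3, seed=9))

scan = fa.survival_scan(matrix, annots, ["FGFR1"],
                        min_days=30, min_prop=0.1,
                        permutation_reps=200, seed=1)
fit = scan.fits[0]
print(f"{fit.gene} in {fit.cohort}: cutoff={fit.cutoff:.0f} "
      f"({fit.n_low} low / {fit.n_high} high)")
print(f"  HR(high vs low) = {fit.hazard_ratio:.2f} "
      f"[{fit.ci_low:.2f}, {fit.ci_high:.2f}], Cox p = {fit.cox_p:.2g}")
print(f"  log-rank chi2 = {fit.logrank_chi2:.1f}, "
      f"naive p = {fit.logrank_p:.2g}, "
      f"selection-corrected p = {fit.permutation_p:.3f}")
print(f"  direction: {fit.direction}")
# HR > 1 recovers the planted adverse effect; the corrected p stays
# significant but is larger than the naive cutpoint-selected p
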
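"""Tumor-vs-normal differential expression on a cohort with a planted signal.

FGFR1 is upregulated 4-fold (log2fc = 2) in tumors; FGFR3 has no planted
effect.  The scan reports the Wilcoxon rank-sum p per gene, the log2 fold
change of group means, and a significance tier (the p < 0.001 tier is the one
emphasized in pan-cancer heat grids).
"""

import fgfr_atlas as fa

genes = [fa.GeneSpec("FGFR1", log2_sd=0.5, log2fc=2.0),
         fa.GeneSpec("FGFR3", log2_sd=0.5)]
matrix, annots = fa.generate_cohort(
    fa.CohortSpec("BLCA", n_tumor=50, n_normal=20, genes=genes, seed=11))

scan = fa.de_scan(matrix, annots, ["FGFR1", "FGFR3"])
for r in scan.results:
    print(f"{r.gene} in {r.cohort}: log2FC={r.log2fc:+.3f}  "
          f"p={r.p_value:.3g}  tier={r.tier}  "
          f"(n={r.n_tumor}T/{r.n_normal}N)")
# FGFR1 recovers the planted log2FC of 2 and lands in the p<0.001 tier;
# FGFR3 stays non-significant
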
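"""Build a small synthetic pan-cancer atlas with known planted effects.

Three cohorts share the default FGF1-23 / FGFR1-4 gene panel; BLCA carries an
adverse survival link on FGFR1 and CHOL an upregulated FGFR1.  The printed
counts confirm the column-wise merge preserves per-cohort sample sizes.
"""

import fgfr_atlas as fa

genes = fa.default_gene_specs()
chol_genes = [
    fa.GeneSpec(g.symbol, g.base_log2_mean, g.log2_sd,
                log2fc=1.5 if g.symbol == "FGFR1" else 0.0)
    for g in genes
]

matrix, annots = fa.generate_pancancer([
    fa.CohortSpec("BLCA", n_tumor=120, n_normal=19, genes=genes,
                  survival_link=fa.SurvivalLink("FGFR1", 0.7), seed=1),
    fa.CohortSpec("CHOL", n_tumor=36, n_normal=9, genes=chol_genes, seed=2),
    fa.CohortSpec("LUSC", n_tumor=100, n_normal=20, genes=genes, seed=3),
])

print(f"atlas: {matrix.shape[0]} genes x {matrix.shape[1]} samples")
for cohort in annots.cohorts:
    print(f"  {cohort}: {len(annots.tumor_samples(cohort))} tumor / "
          f"{len(annots.normal_samples(cohort))} normal")
# each cohort keeps its requested tumor/normal split after the merge
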
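"""Methylation-expression coupling: DEMGs, regional correlation, block
concordance.

A DEMG is a significantly differentially expressed gene (|log2FC| > 0.5)
carrying at least three differentially methylated CpGs (|dM| > 0.2) in its
regulatory regions. Regional correlation regresses log2 expression on the
mean M value of each gene's CpGs per region class; block concordance
compares observed methylation change inside reference genomic intervals with
the change reported for them.
"""

import pandas as pd

import photomics as pm
from photomics.differential import beta_to_m

config = pm.CohortConfig(seed=1)
cohort, truth = pm.generate_cohort(config)
manifest, _, blocks = pm.generate_annotations(config)

expr_diff = pm.differential_expression(cohort)
meth_diff = pm.differential_methylation(cohort)

table, summary = pm.select_demgs(expr_diff, meth_diff, manifest)
print(f"DEMGs among upregulated genes:   {summary['fraction_up']:.1%} "
      f"({summary['n_demg_up']}/{summary['n_up']})")
print(f"DEMGs among downregulated genes: {summary['fraction_down']:.1%} "
      f"({summary['n_demg_down']}/{summary['n_down']})")

meth_m = pd.DataFrame(beta_to_m(cohort.methylation_beta.to_numpy()),
                      index=cohort.methylation_beta.index,
                      columns=cohort.methylation_beta.columns)
regional = {cls: pm.aggregate_regional_methylation(meth_m, manifest, cls)
            for cls in ("Enhancer", "TSS1500", "TSS200", "Exon")}
corr = pm.correlate_expression_methylation(cohort.expression_log2(), regional,
                                           manifest)
n_sig = int((corr["q_value"] < 0.05).sum())
print(f"\nsignificant expression~methylation associations: {n_sig} "
      f"of {len(corr)} gene x region tests")

conc = pm.block_concordance(meth_diff, manifest, blocks)
print(f"\nblocks with significant CpGs: {conc['n_evaluable']}, "
      f"sign-concordant: {conc['n_concordant']}")
# Planted concordant blocks reproduce the reference deltas' signs; the extra
# discordant blocks carry random reference values by design.
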
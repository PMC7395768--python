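"""Paired differential methylation and the hypomethylation gradient.

Runs the paired t statistics on M values, applies BH-FDR, and summarizes the
direction of significant changes overall and by CpG-island relation.
"""

import photomics as pm

config = pm.CohortConfig(seed=1)
cohort, _ = pm.generate_cohort(config)
manifest, _, _ = pm.generate_annotations(config)

meth_diff = pm.differential_methylation(cohort)
summary = pm.hypomethylation_summary(meth_diff, manifest, q_threshold=0.05)

n_sig, frac = summary["overall"]
print(f"significant CpGs (q<0.05): {n_sig} of {len(meth_diff)}"
      f" ({n_sig / len(meth_diff):.1%})")
print(f"hypomethylated among significant: {frac:.1%}")
print("\nper island relation (hypomethylated fraction rises toward islands):")
print(summary["per_island_relation"].round(3).to_string())
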
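import pandas as pd
import pytest

import photomics as pm

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale synthetic cohort at the documented study-design defaults."""
    cfg = pm.CohortConfig(seed=DEFAULT_SEED)
    cohort, truth = pm.generate_cohort(cfg)
    manifest, gene_sets, blocks = pm.generate_annotations(cfg)
    return {"config": cfg, "cohort": cohort, "truth": truth,
            "manifest": manifest, "gene_sets": gene_sets, "blocks": blocks}


@pytest.fixture(scope="session")
def default_differential(default_cohort):
    cohort = default_cohort["cohort"]
    return {
        "expression": pm.differential_expression(cohort),
        "methylation": pm.differential_methylation(cohort),
    }


def tiny_config(**overrides) -> pm.CohortConfig:
    """Scaled-down generator config for fast structural tests."""
    base = dict(
        n_subjects=8,
        n_genes=60,
        n_cpgs=200,
        frac_cpgs_affected=0.2,
        frac_genes_affected=0.3,
        frac_demg=0.0,
        n_med_predictive_features=3,
        n_subtype_signature_genes=4,
        n_subtype_signature_cpgs=6,
        n_shared_pathway_genes=4,
        n_null_gene_sets=2,
        n_blocks=4,
        n_concordant_blocks=0,
        seed=11,
    )
    base.update(overrides)
    return pm.CohortConfig(**base)


@pytest.fixture
def toy_paired_matrix():
    """4-subject paired matrix with hand-checkable differences."""
    samples = [f"S{i}_{c}" for i in range(1, 5) for c in ("ctrl", "irr")]
    sample_table = pd.DataFrame(
        {
            "subject": [s.split("_")[0] for s in samples],
            "condition": ["control" if s.endswith("ctrl") else "irradiated"
                          for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    # paired differences per subject: 0.8, 1.2, 1.0, 1.0
    ctrl = [1.0, 2.0, 3.0, 4.0]
    diffs = [0.8, 1.2, 1.0, 1.0]
    values = []
    for c, d in zip(ctrl, diffs):
        values.extend([c, c + d])
    matrix = pd.DataFrame([values], index=["F1"], columns=samples)
    return matrix, sample_table
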
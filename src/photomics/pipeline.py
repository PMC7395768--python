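"""End-to-end orchestration: simulate/load -> differential -> integration ->
enrichment -> MED models -> fusion subtyping -> pathway predictivity.

A single global seed fans out to per-stage seeds (seed + stage index) so any
stage can be re-run in isolation with the same randomness. Every stage's
artifacts are written under the output directory and listed, in execution
order, in the run manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import IRRADIATED, PairedOmicsCohort
from .differential import (
    beta_to_m,
    differential_expression,
    differential_methylation,
    hypomethylation_summary,
)
from .enrichment import differential_enrichment, zscore_enrichment
from .fusion import FusionParams, subtype_cohort
from .integration import (
    DemgCriteria,
    aggregate_regional_methylation,
    block_concordance,
    correlate_expression_methylation,
    select_demgs,
)
from .med import predict_med_all_levels
from .predictivity import PredictivityParams, predictivity_map
from .synthetic import CohortConfig, generate_annotations, generate_cohort

CORRELATION_CLASSES = ("Enhancer", "TSS1500", "TSS200", "Exon")

_STAGES = ("input", "differential", "integration", "enrichment", "med",
           "fusion", "predictivity")


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` or ``data_paths`` selects the input."""

    outdir: str
    synthetic: CohortConfig | None = None
    data_paths: dict | None = None   # expression/methylation/samples/subjects/
                                     # manifest/gmt/bed
    demg: DemgCriteria = field(default_factory=DemgCriteria)
    fusion: FusionParams = field(default_factory=FusionParams)
    predictivity: PredictivityParams = field(default_factory=PredictivityParams)
    q_threshold: float = 0.05
    med_folds: int = 10
    n_clusters: int | None = None    # None -> eigen-gap estimate
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.data_paths is None):
            raise ValueError(
                "provide exactly one of a synthetic cohort config or data paths"
            )
        if self.data_paths is not None:
            required = {"expression", "methylation", "samples", "subjects",
                        "manifest", "gmt", "bed"}
            missing = required - set(self.data_paths)
            if missing:
                raise ValueError(f"data_paths missing key(s): {sorted(missing)}")


def _stage_seed(base: int, stage: str) -> int:
    return int(base) + _STAGES.index(stage)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order.

    Returns the run manifest: ordered artifact paths plus a ``summary`` dict
    (also written as JSON) with the headline numbers of every stage. Any
    stage failure raises ``RuntimeError`` naming the stage; artifacts of
    completed stages remain on disk.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    artifacts: list[str] = []
    summary: dict = {"seed": int(config.seed)}

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def _save(df: pd.DataFrame, name: str, index_label=None) -> str:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index_label=index_label)
        artifacts.append(path)
        return path

    # ---- input ----------------------------------------------------------
    def _input():
        if config.synthetic is not None:
            cohort, truth = generate_cohort(config.synthetic)
            manifest, gene_sets, blocks = generate_annotations(config.synthetic)
            paths = pio.write_cohort(cohort, os.path.join(outdir, "cohort"))
            artifacts.extend(paths.values())
            tpath = os.path.join(outdir, "cohort", "ground_truth.json")
            truth.to_json(tpath)
            artifacts.append(tpath)
        else:
            p = config.data_paths
            cohort = pio.load_dataset(p["expression"], p["methylation"],
                                      p["samples"], p["subjects"])
            manifest, gene_sets, blocks = pio.load_annotations(
                p["manifest"], p["gmt"], p["bed"]
            )
        return cohort, manifest, gene_sets, blocks

    cohort, manifest, gene_sets, blocks = _run("input", _input)

    expr_log = cohort.expression_log2()
    meth_m = pd.DataFrame(
        beta_to_m(cohort.methylation_beta.to_numpy()),
        index=cohort.methylation_beta.index,
        columns=cohort.methylation_beta.columns,
    )

    # ---- differential ---------------------------------------------------
    def _differential():
        expr_diff = differential_expression(cohort)
        meth_diff = differential_methylation(cohort)
        _save(expr_diff, "differential_expression.tsv", "feature_id")
        _save(meth_diff, "differential_methylation.tsv", "feature_id")
        hypo = hypomethylation_summary(meth_diff, manifest, config.q_threshold)
        return expr_diff, meth_diff, hypo

    expr_diff, meth_diff, hypo = _run("differential", _differential)
    n_sig, frac_hypo = hypo["overall"]
    summary["n_significant_cpgs"] = n_sig
    summary["hypo_fraction_overall"] = frac_hypo
    summary["hypo_fraction_per_island_relation"] = (
        hypo["per_island_relation"]["fraction_hypo"].to_dict()
    )

    # ---- integration ----------------------------------------------------
    def _integration():
        table, demg_summary = select_demgs(expr_diff, meth_diff, manifest,
                                           config.demg)
        _save(table, "demg_table.tsv", "gene_id")
        regional = {
            cls: aggregate_regional_methylation(meth_m, manifest, cls)
            for cls in CORRELATION_CLASSES
        }
        corr = correlate_expression_methylation(expr_log, regional, manifest)
        _save(corr, "expression_methylation_correlations.tsv")
        conc = block_concordance(meth_diff, manifest, blocks, config.q_threshold)
        _save(conc["table"], "block_concordance.tsv")
        return demg_summary, corr, conc

    demg_summary, corr, conc = _run("integration", _integration)
    summary["demg_fraction_up"] = demg_summary["fraction_up"]
    summary["demg_fraction_down"] = demg_summary["fraction_down"]
    summary["n_significant_correlations"] = int(
        (corr["q_value"] < config.q_threshold).sum()
    ) if len(corr) else 0
    summary["block_concordance_r"] = conc["pearson_r"]
    summary["n_concordant_blocks"] = conc["n_concordant"]

    # ---- enrichment -----------------------------------------------------
    def _enrichment():
        scores = zscore_enrichment(expr_log, gene_sets)
        _save(scores, "enrichment_scores.tsv", "gene_set")
        diff = differential_enrichment(scores, cohort.sample_table)
        _save(diff, "differential_enrichment.tsv", "gene_set")
        return diff

    enr_diff = _run("enrichment", _enrichment)
    summary["n_significant_pathways"] = int(
        (enr_diff["q_value"] < config.q_threshold).sum()
    )

    # ---- MED models -----------------------------------------------------
    def _med():
        reports = predict_med_all_levels(
            cohort, outer_folds=min(config.med_folds, cohort.n_subjects),
            seed=_stage_seed(config.seed, "med"),
        )
        for level, rep in reports.items():
            _save(rep.predictions.to_frame(), f"med_predictions_{level}.tsv",
                  "sample_id")
        return reports

    med_reports = _run("med", _med)
    summary["med_metrics"] = {lvl: rep.to_dict() for lvl, rep in med_reports.items()}

    # ---- fusion subtyping ----------------------------------------------
    irr_samples = cohort.sample_table.index[
        cohort.sample_table["condition"] == IRRADIATED
    ]
    med_irr = cohort.med_per_sample().loc[irr_samples]

    def _fusion():
        res = subtype_cohort(
            expr_log[irr_samples], meth_m[irr_samples], med_irr,
            params=config.fusion, n_clusters=config.n_clusters,
            seed=_stage_seed(config.seed, "fusion"),
        )
        _save(res["network"].to_frame(), "fused_network.tsv", "sample_id")
        _save(res["labels"].to_frame(), "subtype_labels.tsv", "sample_id")
        return res

    fus = _run("fusion", _fusion)
    summary["best_k"] = int(fus["best_k"])
    labels = fus["labels"]
    summary["subtype_sizes"] = labels.value_counts().sort_index().to_dict()

    # ---- pathway predictivity ------------------------------------------
    subject_of = cohort.sample_table.loc[labels.index, "subject"]
    subtype_assignment = pd.Series(labels.to_numpy(), index=subject_of.to_numpy())

    def _predictivity():
        params = PredictivityParams(
            C=config.predictivity.C, folds=config.predictivity.folds,
            repeats=config.predictivity.repeats,
            seed=_stage_seed(config.seed, "predictivity"),
        )
        pm = predictivity_map(expr_log, cohort.sample_table,
                              subtype_assignment, gene_sets, params)
        _save(pm.accuracy, "predictivity_unscaled.tsv", "gene_set")
        _save(pm.scaled, "predictivity_scaled.tsv", "gene_set")
        _save(pm.row_mean.to_frame("row_mean"), "predictivity_row_means.tsv",
              "gene_set")
        return pm

    pm = _run("predictivity", _predictivity)
    summary["top_pathways_per_subtype"] = {
        str(st): pm.accuracy[st].nlargest(3).index.tolist()
        for st in pm.accuracy.columns
    }

    summary_path = os.path.join(outdir, "summary.json")
    pio.write_json(summary, summary_path)
    artifacts.append(summary_path)
    manifest_doc = {"artifacts": artifacts, "summary": summary}
    pio.write_json(manifest_doc, os.path.join(outdir, "run_manifest.json"))
    return manifest_doc
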
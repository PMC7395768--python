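"""Readers/writers for the plain-text formats the pipeline touches.

Matrices and metadata travel as TSV, gene sets as MSigDB-dialect GMT,
reference genomic blocks as BED4+ (0-based half-open, optional signed delta
in column 4), configs as YAML and ground truth as JSON. Manifest gene links
are serialized inline as ``GENE|CLASS`` pairs separated by ``;``.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CpGManifest,
    GenomicBlock,
    PairedOmicsCohort,
)
from .synthetic import CohortConfig

DEFAULT_BETA_EPS = 1e-6


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: PairedOmicsCohort, outdir: str) -> dict:
    """Write the four cohort tables as TSV; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression_tpm.tsv"),
        "methylation": os.path.join(outdir, "methylation_beta.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "subjects": os.path.join(outdir, "subjects.tsv"),
    }
    cohort.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    cohort.methylation_beta.rename_axis("cpg_id").to_csv(paths["methylation"], sep="\t")
    cohort.sample_table.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    cohort.subject_table.rename_axis("subject").to_csv(paths["subjects"], sep="\t")
    return paths


def load_dataset(expression_path: str, methylation_path: str,
                 samples_path: str, subjects_path: str,
                 beta_eps: float = DEFAULT_BETA_EPS) -> PairedOmicsCohort:
    """Load and validate a paired cohort from TSV files.

    Beta values exactly 0 or 1 are clamped into (0, 1) by ``beta_eps``;
    values outside [0, 1] are a hard error. Pairing (one control + one
    irradiated sample per subject) is verified and violations name the
    offending subject or sample.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    meth = pd.read_csv(methylation_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    subjects = pd.read_csv(subjects_path, sep="\t", index_col=0)

    for name, mat in (("expression", expr), ("methylation", meth)):
        if not mat.index.is_unique:
            dups = mat.index[mat.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row id(s) in {name} matrix: {dups[:5]}")
        missing = set(mat.columns) - set(samples.index)
        if missing:
            raise ValueError(
                f"{name} column(s) missing from sample metadata: {sorted(missing)}"
            )
        extra = set(samples.index) - set(mat.columns)
        if extra:
            raise ValueError(
                f"sample metadata row(s) missing from {name} matrix: {sorted(extra)}"
            )

    beta = meth.to_numpy(dtype=float)
    if (beta < 0).any() or (beta > 1).any():
        raise ValueError("Beta values outside [0, 1] encountered")
    beta = np.clip(beta, beta_eps, 1.0 - beta_eps)
    meth = pd.DataFrame(beta, index=meth.index, columns=meth.columns)

    order = samples.index
    return PairedOmicsCohort(
        expression=expr[order],
        methylation_beta=meth[order],
        sample_table=samples,
        subject_table=subjects,
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_manifest(manifest: CpGManifest, path: str) -> None:
    links_by_cpg = {}
    for row in manifest.links.itertuples(index=False):
        links_by_cpg.setdefault(row.cpg_id, []).append(
            f"{row.gene_id}|{row.region_class}"
        )
    out = manifest.sites.copy()
    out["gene_links"] = [
        ";".join(links_by_cpg.get(cpg, [])) for cpg in out.index
    ]
    out.rename_axis("cpg_id").to_csv(path, sep="\t")


def load_manifest(path: str) -> CpGManifest:
    df = pd.read_csv(path, sep="\t", dtype={"gene_links": str},
                     keep_default_na=False, na_values=[])
    if df["cpg_id"].duplicated().any():
        dups = df.loc[df["cpg_id"].duplicated(), "cpg_id"].unique().tolist()
        raise ValueError(f"duplicated cpg_id(s) in manifest: {dups[:5]}")
    df["position"] = df["position"].astype(int)
    link_rows = []
    for cpg, raw in zip(df["cpg_id"], df["gene_links"]):
        if not raw:
            continue
        for token in raw.split(";"):
            gene, _, cls = token.partition("|")
            link_rows.append((cpg, gene, cls))
    sites = df.set_index("cpg_id")[["chromosome", "position", "island_relation"]]
    links = pd.DataFrame(link_rows, columns=["cpg_id", "gene_id", "region_class"])
    return CpGManifest(sites=sites, links=links)


def write_gmt(gene_sets: dict, path: str, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def load_gmt(path: str) -> dict:
    """Parse a GMT file into {set name: set of genes}; malformed lines error
    with their line number."""
    gene_sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected name, description "
                    f"and >=1 gene, got {len(parts)} field(s)"
                )
            name = parts[0]
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"malformed GMT line {lineno}: empty gene list")
            gene_sets[name] = genes
    return gene_sets


def flag_missing_genes(gene_sets: dict, expressed_genes) -> dict:
    """Set name -> genes absent from the expression matrix (retained, flagged)."""
    expressed = set(expressed_genes)
    return {name: sorted(set(genes) - expressed)
            for name, genes in gene_sets.items()
            if set(genes) - expressed}


def write_blocks_bed(blocks, path: str) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{b.reference_delta}"
                     f"\t{b.block_id}\n")


def load_blocks_bed(path: str) -> list:
    """BED4+ reader: chrom, start, end and optional delta / name columns."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            delta = float(parts[3]) if len(parts) > 3 else float("nan")
            block_id = parts[4] if len(parts) > 4 else f"block{len(blocks):03d}"
            blocks.append(GenomicBlock(block_id, chrom, start, end, delta))
    return blocks


def load_annotations(manifest_path: str, gmt_path: str, bed_path: str):
    """Load manifest + gene sets + blocks together (validated)."""
    return load_manifest(manifest_path), load_gmt(gmt_path), load_blocks_bed(bed_path)


# ---------------------------------------------------------------------------
# config / misc
# ---------------------------------------------------------------------------

def write_config(config: CohortConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> CohortConfig:
    with open(path) as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


def write_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
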
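"""Coupling of differential methylation and expression.

Covers four analyses: selection of DEMGs (differentially expressed genes
carrying at least ``min_cpgs`` differentially methylated CpGs in regulatory
regions), aggregation of CpG M values into per-gene regional means,
gene-by-region linear models of expression on mean methylation, and
concordance of observed methylation changes with reference genomic blocks
(e.g. regions previously reported as hypomethylated in photoaged skin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CpGManifest
from .differential import bh_adjust

#: region classes that can qualify a CpG for a gene (Intergenic never does)
REGULATORY_CLASSES = ("TSS200", "TSS1500", "Exon", "Enhancer")


@dataclass
class DemgCriteria:
    """Thresholds defining a DEMG."""

    expr_q: float = 0.05
    expr_abs_effect: float = 0.5
    cpg_q: float = 0.05
    cpg_abs_effect: float = 0.2
    min_cpgs: int = 3

    def __post_init__(self) -> None:
        for name in ("expr_q", "expr_abs_effect", "cpg_q", "cpg_abs_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")


def select_demgs(expr_diff: pd.DataFrame, meth_diff: pd.DataFrame,
                 manifest: CpGManifest,
                 criteria: DemgCriteria | None = None):
    """Flag DEMGs and summarize their share among up-/down-regulated genes.

    A CpG qualifies for a gene iff the manifest links it to that gene through
    a non-Intergenic region class and it passes the CpG thresholds. A gene is
    a DEMG iff it passes the expression thresholds and has at least
    ``min_cpgs`` qualifying CpGs.

    Returns
    -------
    (table, summary)
        ``table``: per differentially tested gene, columns ``direction``
        (+1/-1/0), ``significant_expr`` (bool), ``n_qualifying_cpgs``,
        ``demg``.  ``summary``: dict with ``fraction_up`` / ``fraction_down``
        = share of DEMGs among significantly up-/down-regulated genes, plus
        the counts behind them.
    """
    criteria = criteria or DemgCriteria()
    qual_cpgs = meth_diff[
        (meth_diff["q_value"] < criteria.cpg_q)
        & (meth_diff["effect"].abs() > criteria.cpg_abs_effect)
    ].index
    links = manifest.links
    reg_links = links[links["region_class"].isin(REGULATORY_CLASSES)]
    qual_links = reg_links[reg_links["cpg_id"].isin(qual_cpgs)]
    # a CpG linked to one gene through several classes counts once
    counts = qual_links.drop_duplicates(["cpg_id", "gene_id"]) \
                       .groupby("gene_id").size()

    known_genes = set(links["gene_id"])
    orphans = [g for g in expr_diff.index if g not in known_genes]
    if orphans:
        warnings.warn(
            f"{len(orphans)} gene(s) in the differential table have no "
            "manifest CpG links; counted with 0 qualifying CpGs"
        )

    sig_expr = (expr_diff["q_value"] < criteria.expr_q) & \
               (expr_diff["effect"].abs() > criteria.expr_abs_effect)
    n_qual = counts.reindex(expr_diff.index).fillna(0).astype(int)
    table = pd.DataFrame(
        {
            "direction": np.sign(expr_diff["effect"]).astype(int),
            "significant_expr": sig_expr,
            "n_qualifying_cpgs": n_qual,
            "demg": sig_expr & (n_qual >= criteria.min_cpgs),
        },
        index=expr_diff.index,
    )
    up = table[table["significant_expr"] & (table["direction"] > 0)]
    down = table[table["significant_expr"] & (table["direction"] < 0)]
    summary = {
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "n_demg_up": int(up["demg"].sum()),
        "n_demg_down": int(down["demg"].sum()),
        "fraction_up": float(up["demg"].mean()) if len(up) else float("nan"),
        "fraction_down": float(down["demg"].mean()) if len(down) else float("nan"),
    }
    return table, summary


def aggregate_regional_methylation(meth_m: pd.DataFrame, manifest: CpGManifest,
                                   region_class: str) -> pd.DataFrame:
    """gene x sample matrix of unweighted mean M over a gene's CpGs of one class.

    Rows exist only for genes with at least one linked CpG of the class; a
    CpG linked to two genes contributes to both rows.
    """
    from .cohort import REGION_CLASSES

    if region_class not in REGION_CLASSES:
        raise ValueError(f"unknown region class: {region_class!r}")
    links = manifest.links
    sel = links[(links["region_class"] == region_class)
                & links["cpg_id"].isin(meth_m.index)]
    if sel.empty:
        warnings.warn(f"no CpGs with class {region_class!r}; empty matrix")
        return pd.DataFrame(columns=meth_m.columns)
    sel = sel.drop_duplicates(["cpg_id", "gene_id"])
    values = meth_m.loc[sel["cpg_id"]].to_numpy()
    out = pd.DataFrame(values, columns=meth_m.columns)
    out["gene_id"] = sel["gene_id"].to_numpy()
    return out.groupby("gene_id").mean()


def regional_cpg_counts(manifest: CpGManifest, region_class: str) -> pd.Series:
    """Number of distinct CpGs of one region class linked to each gene."""
    links = manifest.links
    sel = links[links["region_class"] == region_class]
    return sel.drop_duplicates(["cpg_id", "gene_id"]).groupby("gene_id").size()


def correlate_expression_methylation(
        expr_log: pd.DataFrame, regional_meth: dict,
        manifest: CpGManifest | None = None,
        min_samples: int = 4) -> pd.DataFrame:
    """Linear models of log2 expression on regional mean methylation.

    For every gene x region-class pair with data, a simple regression across
    all samples (both conditions pooled) yields slope, Pearson r and the
    slope's t-test p-value (n-2 df); BH correction is applied jointly across
    all tested pairs. Pairs where either variable has zero variance are
    skipped.

    Parameters
    ----------
    regional_meth
        mapping region class -> gene x sample mean-M matrix (output of
        :func:`aggregate_regional_methylation`).
    """
    records = []
    for cls, meth in regional_meth.items():
        counts = (regional_cpg_counts(manifest, cls)
                  if manifest is not None else pd.Series(dtype=int))
        genes = meth.index.intersection(expr_log.index)
        if not len(genes):
            continue
        shared = meth.columns.intersection(expr_log.columns)
        if len(shared) < min_samples:
            raise ValueError(
                f"need >= {min_samples} shared samples, got {len(shared)}"
            )
        x = meth.loc[genes, shared].to_numpy(dtype=float)
        y = expr_log.loc[genes, shared].to_numpy(dtype=float)
        n = x.shape[1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        sxx = (xc * xc).sum(axis=1)
        syy = (yc * yc).sum(axis=1)
        sxy = (xc * yc).sum(axis=1)
        ok = (sxx > 0) & (syy > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            r = sxy / np.sqrt(sxx * syy)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        for gi, gene in enumerate(genes):
            if not ok[gi]:
                continue
            records.append((gene, cls, int(counts.get(gene, 1)),
                            float(slope[gi]), float(r[gi]),
                            float(min(p[gi], 1.0))))
    table = pd.DataFrame(
        records, columns=["gene_id", "region_class", "n_cpgs", "slope",
                          "pearson_r", "p_value"],
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table


def block_concordance(meth_diff: pd.DataFrame, manifest: CpGManifest,
                      blocks, q_threshold: float = 0.05) -> dict:
    """Compare observed methylation change per reference block with its
    reported delta.

    Membership uses the 0-based half-open block convention against 1-based
    manifest positions (``start < position <= end``). Blocks without
    significant CpGs are reported but excluded from the overall Pearson r;
    ``concordant`` means the sign of the mean observed effect matches the
    sign of the reference delta.
    """
    if not len(blocks):
        raise ValueError("block list is empty")
    sites = manifest.sites
    sig = meth_diff[meth_diff["q_value"] < q_threshold]
    sig_sites = sites.loc[sites.index.intersection(sig.index)]
    known_chroms = set(sites["chromosome"])
    rows = []
    for b in blocks:
        if b.chromosome not in known_chroms:
            warnings.warn(f"block {b.block_id} on {b.chromosome} not in manifest; skipped")
            continue
        on_chrom = sig_sites[sig_sites["chromosome"] == b.chromosome]
        inside = on_chrom[(on_chrom["position"] > b.start)
                          & (on_chrom["position"] <= b.end)]
        n_sig = int(len(inside))
        mean_effect = float(sig.loc[inside.index, "effect"].mean()) if n_sig else float("nan")
        match = bool(np.sign(mean_effect) == np.sign(b.reference_delta)) if n_sig else None
        rows.append((b.block_id, n_sig, mean_effect, b.reference_delta, match))
    table = pd.DataFrame(
        rows, columns=["block_id", "n_sig_cpgs", "mean_effect",
                       "reference_delta", "sign_match"],
    ).set_index("block_id")
    used = table[table["n_sig_cpgs"] > 0]
    if len(used) >= 2 and used["mean_effect"].std() > 0 and used["reference_delta"].std() > 0:
        r = float(stats.pearsonr(used["mean_effect"], used["reference_delta"])[0])
    else:
        r = float("nan")
    return {
        "table": table,
        "pearson_r": r,
        "n_concordant": int((used["sign_match"] == True).sum()),  # noqa: E712
        "n_evaluable": int(len(used)),
    }
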
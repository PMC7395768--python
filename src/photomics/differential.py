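"""Paired differential statistics with Benjamini-Hochberg FDR control.

Both molecular levels are tested the same way: per feature, the within-subject
difference d_s = x(irradiated, s) - x(control, s) is summarized by a one-sample
t test (effect = mean difference, t = mean / (sd / sqrt(n)), two-sided p from
the t distribution with n-1 degrees of freedom), followed by BH adjustment
across all features of the matrix. Expression enters as log2(TPM+1) and
methylation as M values, so the "effect" column is a log2 fold-change for
expression and a delta-M (itself a log2-odds difference) for methylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTROL, IRRADIATED, CpGManifest, PairedOmicsCohort

#: floor applied to a zero standard deviation of paired differences
SD_FLOOR = 1e-12

#: marker emitted when a summary fraction has an empty denominator
UNDEFINED = float("nan")


def beta_to_m(beta):
    """Convert Beta values in (0, 1) to M values, M = log2(Beta / (1 - Beta)).

    M values are approximately homoscedastic across the methylation range,
    which makes them the preferred scale for testing.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("Beta values must lie strictly inside (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: Beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return out if out.ndim else float(out)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    With p sorted ascending, q_(i) = min_{j >= i} p_(j) * m / j, capped at 1,
    returned in the original order. Ties share a q value by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def paired_differential(matrix: pd.DataFrame,
                        sample_table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature paired t statistics for irradiated vs control.

    Parameters
    ----------
    matrix
        feature x sample values on the analysis scale (log2(TPM+1) or M).
    sample_table
        indexed by sample id with columns ``subject`` and ``condition``;
        every subject must contribute exactly one sample per condition.

    Returns
    -------
    DataFrame indexed by feature id with columns ``effect``, ``t``,
    ``p_value``, ``q_value`` and ``degenerate`` (True where the paired
    differences had zero variance and the sd floor was applied).
    """
    subjects = sample_table["subject"].unique()
    if len(subjects) < 3:
        raise ValueError("paired differential analysis needs >= 3 subjects")
    cols = {}
    for cond in (CONTROL, IRRADIATED):
        sub = sample_table[sample_table["condition"] == cond]
        mapping = pd.Series(sub.index.values, index=sub["subject"].values)
        if mapping.index.duplicated().any() or len(mapping) != len(subjects):
            bad = sorted(set(subjects) ^ set(mapping.index))
            raise ValueError(
                f"pairing broken for condition {cond!r}; offending subject(s): {bad}"
            )
        cols[cond] = mapping.reindex(subjects).to_numpy()
    missing = (set(cols[CONTROL]) | set(cols[IRRADIATED])) - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix lacks sample column(s): {sorted(missing)}")

    d = matrix[cols[IRRADIATED]].to_numpy() - matrix[cols[CONTROL]].to_numpy()
    n = d.shape[1]
    effect = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd < SD_FLOOR
    sd_safe = np.maximum(sd, SD_FLOOR)
    t = effect / (sd_safe / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # exact-zero effect with zero spread carries no evidence at all
    p = np.where(degenerate & (effect == 0.0), 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "degenerate": degenerate,
        },
        index=matrix.index.rename("feature_id"),
    )


def differential_expression(cohort: PairedOmicsCohort) -> pd.DataFrame:
    """Paired differential expression on log2(TPM+1)."""
    return paired_differential(cohort.expression_log2(), cohort.sample_table)


def differential_methylation(cohort: PairedOmicsCohort) -> pd.DataFrame:
    """Paired differential methylation on M values."""
    m_values = pd.DataFrame(
        beta_to_m(cohort.methylation_beta.to_numpy()),
        index=cohort.methylation_beta.index,
        columns=cohort.methylation_beta.columns,
    )
    return paired_differential(m_values, cohort.sample_table)


def hypomethylation_summary(meth_diff: pd.DataFrame, manifest: CpGManifest,
                            q_threshold: float = 0.05) -> dict:
    """Fraction of significant CpGs losing methylation, overall and by island relation.

    A CpG counts as hypomethylated when q < ``q_threshold`` and its effect is
    strictly negative (a zero effect is counted as non-hypo). With no
    significant CpGs the fractions are reported as NaN rather than 0.

    Returns
    -------
    dict with keys ``overall`` -> (n_significant, fraction_hypo) and
    ``per_island_relation`` -> DataFrame indexed OpenSea..Island with columns
    ``n_significant`` and ``fraction_hypo``.
    """
    sig = meth_diff[meth_diff["q_value"] < q_threshold]
    missing = set(sig.index) - set(manifest.cpg_ids)
    if missing:
        raise ValueError(
            f"significant CpG(s) absent from manifest: {sorted(missing)[:5]}"
        )
    relation = manifest.sites["island_relation"].reindex(sig.index)
    hypo = sig["effect"] < 0

    def _frac(mask):
        return float(hypo[mask].mean()) if int(mask.sum()) else UNDEFINED

    from .cohort import ISLAND_RELATIONS

    rows = []
    for rel in ISLAND_RELATIONS:
        mask = relation == rel
        rows.append((int(mask.sum()), _frac(mask)))
    per_rel = pd.DataFrame(
        rows, index=pd.Index(ISLAND_RELATIONS, name="island_relation"),
        columns=["n_significant", "fraction_hypo"],
    )
    n_sig = int(len(sig))
    overall = float(hypo.mean()) if n_sig else UNDEFINED
    return {"overall": (n_sig, overall), "per_island_relation": per_rel}
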
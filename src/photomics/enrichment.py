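"""Sample-wise combined z-score gene-set enrichment.

Each gene's log2(TPM+1) profile is standardized across samples (sample sd,
ddof=1); a set's score in a sample is the sum of its member z-scores divided
by sqrt(k), k = number of set members present with nonzero variance. Under a
per-gene standard-normal null the combined score is again standard normal,
which is what makes paired differential testing of the scores well behaved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .differential import paired_differential


def zscore_enrichment(expr_log: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """gene_set x sample matrix of combined z scores.

    Zero-variance genes cannot be standardized and are dropped from every set
    (with a warning); sets with no usable genes are omitted.
    """
    if expr_log.shape[1] < 2:
        raise ValueError("z-score enrichment needs >= 2 samples")
    values = expr_log.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-variance gene(s) dropped from sets"
        )
    z = np.full_like(values, np.nan)
    z[usable] = ((values[usable] - values[usable].mean(axis=1, keepdims=True))
                 / sd[usable, None])
    zdf = pd.DataFrame(z, index=expr_log.index, columns=expr_log.columns)

    rows, names = [], []
    for name, genes in gene_sets.items():
        members = [g for g in genes if g in zdf.index and usable[zdf.index.get_loc(g)]]
        if not members:
            warnings.warn(f"gene set {name!r} has no expressed genes; omitted")
            continue
        score = zdf.loc[members].to_numpy().sum(axis=0) / np.sqrt(len(members))
        rows.append(score)
        names.append(name)
    return pd.DataFrame(rows, index=pd.Index(names, name="gene_set"),
                        columns=expr_log.columns)


def differential_enrichment(scores: pd.DataFrame,
                            sample_table: pd.DataFrame) -> pd.DataFrame:
    """Paired irradiated-vs-control test per gene set (same contract as the
    feature-level paired differential)."""
    return paired_differential(scores, sample_table)
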
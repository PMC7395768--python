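"""Per-gene-set SVM predictivity of irradiation status.

Each gene set is scored by how well an RBF-kernel support-vector classifier,
restricted to the set's expressed genes, discriminates irradiated from
control samples under 5x5-fold repeated stratified cross-validation
(gamma = 1 / number of expressed set genes, C = 1). Scoring per molecular
phototype yields a gene-set x subtype accuracy map; rows are min-max scaled
for display, with the unscaled row mean reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import IRRADIATED


@dataclass
class PredictivityParams:
    """Repeated-CV settings for the per-set classifiers."""

    C: float = 1.0
    folds: int = 5
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def pathway_score(expr_log: pd.DataFrame, labels: pd.Series, gene_set,
                  params: PredictivityParams | None = None) -> float:
    """Mean repeated-CV accuracy of irradiation-status prediction from one set.

    ``labels`` holds the condition per sample; features are standardized
    within each training fold. If the smaller class has fewer samples than
    ``folds``, the fold count is reduced to that class size (warned).
    """
    params = params or PredictivityParams()
    genes = [g for g in sorted(gene_set) if g in expr_log.index]
    if not genes:
        raise ValueError("gene set has no expressed genes")
    y = (labels.reindex(expr_log.columns) == IRRADIATED).to_numpy()
    class_sizes = [int((~y).sum()), int(y.sum())]
    if min(class_sizes) < 2:
        raise ValueError("need >= 2 samples per class")
    folds = params.folds
    if min(class_sizes) < folds:
        folds = min(class_sizes)
        warnings.warn(
            f"smallest class has {min(class_sizes)} samples; folds reduced to {folds}"
        )
    X = expr_log.loc[genes].to_numpy(dtype=float).T  # samples x set genes
    gamma = 1.0 / len(genes)
    accs = []
    for rep in range(params.repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=params.seed * 1000 + rep)
        for tr, te in skf.split(X, y):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="rbf", C=params.C, gamma=gamma)
            clf.fit((X[tr] - mu) / sd, y[tr])
            pred = clf.predict((X[te] - mu) / sd)
            accs.append(float((pred == y[te]).mean()))
    return float(np.mean(accs))


@dataclass
class PredictivityMap:
    """gene_set x subtype accuracy matrix with row means and a scaled view."""

    accuracy: pd.DataFrame     # unscaled, values in [0, 1]
    row_mean: pd.Series        # arithmetic mean over subtype columns
    scaled: pd.DataFrame       # per-row min-max; zero-range rows map to 0.5


def predictivity_map(expr_log: pd.DataFrame, sample_table: pd.DataFrame,
                     subtype_assignment: pd.Series, gene_sets: dict,
                     params: PredictivityParams | None = None) -> PredictivityMap:
    """Score every gene set within every molecular phototype.

    ``subtype_assignment`` maps subject -> subtype label; each subtype's
    score uses both conditions of its subjects' paired samples. Subtypes
    with fewer than 2 subjects are omitted with a warning; sets with no
    expressed genes are omitted with a warning.
    """
    params = params or PredictivityParams()
    missing = set(sample_table["subject"]) - set(subtype_assignment.index)
    if missing:
        raise ValueError(
            f"subtype assignment missing subject(s): {sorted(missing)}"
        )
    labels = sample_table["condition"]
    subtypes = sorted(pd.unique(subtype_assignment))
    columns = {}
    for st in subtypes:
        subjects = subtype_assignment.index[subtype_assignment == st]
        if len(subjects) < 2:
            warnings.warn(f"subtype {st} has < 2 subjects; column omitted")
            continue
        samples = sample_table.index[sample_table["subject"].isin(subjects)]
        scores = {}
        for name, genes in gene_sets.items():
            usable = [g for g in genes if g in expr_log.index]
            if not usable:
                warnings.warn(f"gene set {name!r} has no expressed genes; omitted")
                continue
            scores[name] = pathway_score(
                expr_log[samples], labels.loc[samples], usable, params
            )
        columns[st] = pd.Series(scores)
    acc = pd.DataFrame(columns).dropna()
    acc.index.name = "gene_set"
    row_mean = acc.mean(axis=1)
    rng_ = acc.max(axis=1) - acc.min(axis=1)
    scaled = acc.sub(acc.min(axis=1), axis=0).div(rng_.replace(0, np.nan), axis=0)
    scaled = scaled.fillna(0.5)
    return PredictivityMap(accuracy=acc, row_mean=row_mean, scaled=scaled)
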
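"""Cross-validated L1-regularized prediction of the minimal erythema dose.

MED (mJ/cm^2) is a subject-level phenotype; both samples of a subject enter
the feature matrix (the model should predict UV sensitivity irrespective of
prior exposure) and share the subject's MED target. Features are expression
log2(TPM+1) and/or methylation M values. The penalty is chosen per outer fold
by inner 5-fold cross-validation over a 100-point log-spaced path from
lambda_max down to 1e-4*lambda_max, with standardization fit on each training
split only. Outer folds are grouped by subject so no subject straddles a
train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold

from .cohort import IRRADIATED, PairedOmicsCohort
from .differential import beta_to_m

LEVELS = ("expression", "methylation", "combined")
N_ALPHAS = 100
ALPHA_MIN_RATIO = 1e-4


def assemble_features(cohort: PairedOmicsCohort, level: str = "combined"):
    """Build the sample x feature matrix and MED target for one data level.

    Expression features are log2(TPM+1) and methylation features M values;
    ``combined`` concatenates both with level-tagged ids (``expr:``/``meth:``
    prefixes, so collisions are impossible by construction). Columns are
    standardized with full-data statistics (recorded in the returned frame's
    ``attrs`` for reuse); zero-variance features are dropped with a warning.

    Returns
    -------
    (features, med)
        ``features``: DataFrame samples x features, standardized.
        ``med``: Series of the subject MED repeated for both samples.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    parts = []
    if level in ("expression", "combined"):
        e = cohort.expression_log2().T
        e.columns = [f"expr:{g}" for g in e.columns]
        parts.append(e)
    if level in ("methylation", "combined"):
        m = pd.DataFrame(
            beta_to_m(cohort.methylation_beta.to_numpy()),
            index=cohort.methylation_beta.index,
            columns=cohort.methylation_beta.columns,
        ).T
        m.columns = [f"meth:{c}" for c in m.columns]
        parts.append(m)
    X = pd.concat(parts, axis=1)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance feature(s) dropped")
    X = (X.loc[:, keep] - mean[keep]) / sd[keep]
    X.attrs["standardization"] = {"mean": mean[keep], "sd": sd[keep]}
    med = cohort.med_per_sample().reindex(X.index)
    return X, med


@dataclass
class MedModelReport:
    """Out-of-fold predictions plus summary metrics for one data level."""

    level: str
    predictions: pd.Series            # per sample, out-of-fold, mJ/cm^2
    mae: float                        # median absolute error, mJ/cm^2
    pearson_r: float
    r_squared: float
    per_fold_alpha: list
    coefficients: pd.Series           # nonzero coefficients of full-data fit
    per_condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "per_fold_alpha": list(map(float, self.per_fold_alpha)),
            "n_nonzero_coefficients": int(len(self.coefficients)),
            "per_condition": self.per_condition,
        }


def _alpha_path(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """100 log-spaced penalties from lambda_max (all-zero solution) down."""
    n = X.shape[0]
    yc = y - y.mean()
    alpha_max = np.abs(X.T @ yc).max() / n
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max),
                       np.log10(alpha_max * ALPHA_MIN_RATIO), N_ALPHAS)


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    out = [(train - mu) / sd]
    out.extend((o - mu) / sd for o in others)
    return out


def _fit_path(Xtr, ytr, alphas):
    """Warm-started coordinate-descent fits along a penalty path.

    Used only to rank penalties inside the inner CV, so a loose tolerance is
    adequate; the selected penalty is refit tightly on the outer split.
    """
    model = Lasso(alpha=alphas[0], warm_start=True, max_iter=1000, tol=1e-3)
    coefs, intercepts = [], []
    for a in alphas:
        model.set_params(alpha=a)
        model.fit(Xtr, ytr)
        coefs.append(model.coef_.copy())
        intercepts.append(model.intercept_)
    return np.array(coefs), np.array(intercepts)


def _inner_select_alpha(Xtr, ytr, groups, alphas, inner_folds, rng):
    n_groups = len(np.unique(groups))
    k = min(inner_folds, n_groups)
    mse = np.zeros(len(alphas))
    gkf = GroupKFold(n_splits=k)
    for tr, te in gkf.split(Xtr, ytr, groups):
        Xa, Xb = _standardize(Xtr[tr], Xtr[te])
        coefs, intercepts = _fit_path(Xa, ytr[tr], alphas)
        preds = Xb @ coefs.T + intercepts  # (n_te, n_alphas)
        mse += ((preds - ytr[te][:, None]) ** 2).mean(axis=0)
    return alphas[int(np.argmin(mse))]


def fit_lasso(X, y, alpha: float):
    """Single lasso fit (no standardization); returns (coef, intercept).

    In the penalty -> 0 limit on a well-posed problem this converges to the
    ordinary least-squares solution.
    """
    model = Lasso(alpha=max(alpha, 1e-12), max_iter=200000, tol=1e-10)
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model.coef_.copy(), float(model.intercept_)


def cross_validated_lasso(features: pd.DataFrame, med: pd.Series,
                          sample_table: pd.DataFrame,
                          outer_folds: int = 10, inner_folds: int = 5,
                          seed: int = 0, level: str = "combined",
                          alpha_override: float | None = None) -> MedModelReport:
    """Subject-grouped 10-fold CV lasso prediction of MED.

    Within each outer training split the penalty is selected by inner
    grouped CV minimizing mean squared error; out-of-fold predictions are
    pooled over all samples exactly once. MAE is the median absolute error.
    Metrics are also reported separately for control-only and
    irradiated-only samples.
    """
    subjects = sample_table.loc[features.index, "subject"].to_numpy()
    n_subjects = len(np.unique(subjects))
    if outer_folds > n_subjects:
        raise ValueError(
            f"outer_folds ({outer_folds}) exceeds number of subjects ({n_subjects})"
        )
    if len(features) < 2 * outer_folds:
        raise ValueError("need at least 2 samples per outer fold")
    X = features.to_numpy(dtype=float)
    y = med.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    # shuffle subject order deterministically, then group-fold
    uniq = np.unique(subjects)
    perm = rng.permutation(len(uniq))
    rank = {s: perm[i] for i, s in enumerate(uniq)}
    group_key = np.array([rank[s] for s in subjects])

    preds = np.full(len(y), np.nan)
    fold_alphas = []
    gkf = GroupKFold(n_splits=outer_folds)
    for tr, te in gkf.split(X, y, group_key):
        if alpha_override is None:
            alphas = _alpha_path(*_standardize(X[tr])[:1], y[tr])
            best = _inner_select_alpha(X[tr], y[tr], group_key[tr], alphas,
                                       inner_folds, rng)
        else:
            best = alpha_override
        Xa, Xb = _standardize(X[tr], X[te])
        if np.isinf(best):
            preds[te] = y[tr].mean()  # full shrinkage: intercept-only model
            fold_alphas.append(best)
            continue
        model = Lasso(alpha=best, max_iter=10000, tol=1e-6)
        model.fit(Xa, y[tr])
        preds[te] = model.predict(Xb)
        fold_alphas.append(best)
    assert not np.isnan(preds).any()

    def _metrics(mask) -> dict:
        yy, pp = y[mask], preds[mask]
        mae = float(np.median(np.abs(pp - yy)))
        if np.std(yy) == 0 or np.std(pp) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(yy, pp)[0])
        ss_res = float(((yy - pp) ** 2).sum())
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")
        return {"mae": mae, "pearson_r": r, "r_squared": r2}

    overall = _metrics(np.ones(len(y), dtype=bool))
    cond = sample_table.loc[features.index, "condition"].to_numpy()
    per_condition = {
        c: _metrics(cond == c) for c in np.unique(cond)
    }

    # final full-data fit: penalty = median of fold choices
    final_alpha = float(np.median(fold_alphas))
    if np.isinf(final_alpha):
        coef = pd.Series(dtype=float)
    else:
        Xa, = _standardize(X)
        final = Lasso(alpha=final_alpha, max_iter=10000, tol=1e-6)
        final.fit(Xa, y)
        coef = pd.Series(final.coef_, index=features.columns)
        coef = coef[coef != 0]

    return MedModelReport(
        level=level,
        predictions=pd.Series(preds, index=features.index, name="predicted_med"),
        mae=overall["mae"],
        pearson_r=overall["pearson_r"],
        r_squared=overall["r_squared"],
        per_fold_alpha=fold_alphas,
        coefficients=coef,
        per_condition=per_condition,
    )


def predict_med_all_levels(cohort: PairedOmicsCohort, outer_folds: int = 10,
                           seed: int = 0) -> dict:
    """Run the MED model on expression, methylation and combined features."""
    reports = {}
    for level in LEVELS:
        X, med = assemble_features(cohort, level)
        reports[level] = cross_validated_lasso(
            X, med, cohort.sample_table, outer_folds=outer_folds,
            seed=seed, level=level,
        )
    return reports
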
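"""Feature standardization and the feature-selection suite.

Selection happens strictly on training rows: the Z-score scaler is fitted
on the training split and applied unchanged elsewhere, and every selector
consumes only training features and labels.  The suite: a Mann-Whitney U
prefilter at raw p < 0.05 (no multiple-testing correction by default,
Benjamini-Hochberg available), L1-penalized logistic regression (LASSO),
mutual-information top-n ranking, and recursive feature elimination with a
random forest (Gini importances), plus Pearson correlation analysis of the
surviving features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

logger = logging.getLogger(__name__)


@dataclass
class ScalerState:
    """Per-feature train-split mean/sd (population sd), applied everywhere."""

    mean: pd.Series
    sd: pd.Series
    dropped_constant: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.mean.index)
        return (table[cols] - self.mean) / self.sd


def fit_apply_scaler(
    table: pd.DataFrame, train_rows: np.ndarray
) -> tuple[pd.DataFrame, ScalerState]:
    """Fit Z-scoring on the training rows; return the scaled full table.

    Features constant on the training rows are dropped with a warning.
    """
    train = table.loc[train_rows] if not np.issubdtype(
        np.asarray(train_rows).dtype, np.bool_
    ) else table.loc[np.asarray(train_rows)]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        logger.warning("dropping %d constant feature(s): %s%s",
                       len(constant), constant[:3], "..." if len(constant) > 3 else "")
        mean = mean.drop(constant)
        sd = sd.drop(constant)
    state = ScalerState(mean=mean, sd=sd, dropped_constant=constant)
    return state.transform(table), state


@dataclass
class SelectionResult:
    """Outcome of one selector: kept feature names plus per-feature scores."""

    method: str
    kept_features: list[str]
    scores: pd.Series
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "params": self.params,
                "kept_features": list(self.kept_features),
                "scores": {k: float(v) for k, v in self.scores.items()},
            },
            indent=2,
        )


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def mwu_prefilter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05, correct: bool = False
) -> SelectionResult:
    """Keep features whose two-sided Mann-Whitney U p-value is below alpha.

    p-values use the normal approximation with tie and continuity
    correction; ``correct=True`` switches to Benjamini-Hochberg adjusted
    p-values (off by default: the gate is on raw p < 0.05).
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    g0 = table.loc[labels == np.unique(labels)[0]]
    g1 = table.loc[labels == np.unique(labels)[1]]
    pvals = {}
    for col in table.columns:
        a, b = g0[col].to_numpy(), g1[col].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[col] = 1.0
            continue
        pvals[col] = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    p = pd.Series(pvals)
    gate = p.copy()
    if correct:
        order = np.argsort(p.to_numpy())
        m = len(p)
        adj = np.empty(m)
        ranked = p.to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        gate = pd.Series(np.minimum(adj, 1.0), index=p.index)
    kept = [c for c in table.columns if gate[c] < alpha]
    return SelectionResult(
        method="mwu", kept_features=kept, scores=p,
        params={"alpha": alpha, "correct": correct},
    )


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    penalty_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic selection; the penalty is chosen by CV AUC.

    Kept features are those with nonzero coefficients, ordered by |coef|.
    An all-zero model yields an empty result with a warning, not an error.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    x = table.to_numpy()
    folds = min(cv_folds, int(np.bincount(labels).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    best_c, best_score = None, -np.inf
    for c in penalty_grid:
        model = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", random_state=seed, max_iter=2000
        )
        score = cross_val_score(model, x, labels, cv=cv, scoring="roc_auc").mean()
        if score > best_score:
            best_c, best_score = c, score
    model = LogisticRegression(
        l1_ratio=1.0, C=best_c, solver="liblinear", random_state=seed, max_iter=2000
    ).fit(x, labels)
    coefs = pd.Series(np.abs(model.coef_[0]), index=table.columns)
    kept = list(coefs[coefs > 0].sort_values(ascending=False).index)
    if not kept:
        warnings.warn("LASSO shrank every coefficient to zero; empty selection")
    return SelectionResult(
        method="lasso", kept_features=kept, scores=coefs,
        params={"C": best_c, "cv_auc": float(best_score), "cv_folds": folds},
    )


def mi_select(
    table: pd.DataFrame, labels: np.ndarray, top_n: int = 20, seed: int = 0
) -> SelectionResult:
    """Keep the top-n features by k-nearest-neighbor mutual information."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if top_n > table.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds feature count {table.shape[1]}; clipping"
        )
        top_n = table.shape[1]
    mi = mutual_info_classif(
        table.to_numpy(), labels, n_neighbors=3, random_state=seed
    )
    scores = pd.Series(mi, index=table.columns)
    kept = list(scores.sort_values(ascending=False, kind="stable").index[:top_n])
    return SelectionResult(
        method="mi", kept_features=kept, scores=scores, params={"top_n": top_n}
    )


def rfe_rf_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_keep: int = 20,
    step: float = 0.1,
    seed: int = 0,
    n_estimators: int = 200,
) -> SelectionResult:
    """Recursive feature elimination driven by random-forest Gini importance.

    10% of the remaining features are dropped per iteration by default;
    importances of the final fit are reported.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n_keep = min(n_keep, table.shape[1])
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    if n_keep == table.shape[1]:
        rf.fit(table.to_numpy(), labels)
        scores = pd.Series(rf.feature_importances_, index=table.columns)
        kept = list(scores.sort_values(ascending=False, kind="stable").index)
        return SelectionResult(
            method="rfe_rf", kept_features=kept, scores=scores,
            params={"n_keep": n_keep, "step": step},
        )
    rfe = RFE(estimator=rf, n_features_to_select=n_keep, step=step)
    rfe.fit(table.to_numpy(), labels)
    mask = rfe.support_
    importances = pd.Series(0.0, index=table.columns)
    importances[table.columns[mask]] = rfe.estimator_.feature_importances_
    kept = list(
        importances[mask].sort_values(ascending=False, kind="stable").index
    )
    return SelectionResult(
        method="rfe_rf", kept_features=kept, scores=importances,
        params={"n_keep": n_keep, "step": step},
    )


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix with unit diagonal.

    Correlations involving a constant column are defined as 0 (warned).
    """
    if len(table) < 2:
        raise ValueError("need >= 2 rows for correlations")
    sd = table.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"constant column(s) {constant[:3]}: correlation set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(table.to_numpy(), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)
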
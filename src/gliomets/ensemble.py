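"""Classifier suite, model selection, and the weighted soft-voting ensemble.

Six probabilistic classifiers are supported (Gaussian naive Bayes,
L1 logistic regression, polynomial- and RBF-kernel SVMs, random forest,
gradient-boosted trees).  Hyperparameters are chosen by grid search under
the one-standard-deviation rule in stratified 10-fold cross-validation:
among candidates whose mean CV AUC is within one standard deviation (of the
best candidate's fold scores) of the best mean, the simplest wins, per a
per-kind complexity ordering (stronger regularization, fewer/shallower
trees, lower degree = simpler).

The RSV model is a weighted soft vote of the two best-performing base
classifiers with weight pair omega = (omega1, omega2); the weight grid
defaults to the ratios 1:1, 2:1, 2:3, 4:3, 3:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import calibration_curve
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

DEFAULT_WEIGHT_GRID: tuple[tuple[float, float], ...] = (
    (1, 1), (2, 1), (2, 3), (4, 3), (3, 1),
)

CLASSIFIER_KINDS = (
    "gnb", "logreg_l1", "svm_poly", "svm_rbf", "random_forest",
    "gradient_boosted_trees",
)


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "gnb":
        return GaussianNB(**params)
    if kind == "logreg_l1":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", random_state=seed, max_iter=2000,
            **params,
        )
    if kind == "svm_poly":
        return SVC(kernel="poly", probability=True, random_state=seed, **params)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "gradient_boosted_trees":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0,
            **params,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


# smaller key = simpler model under the one-standard-deviation rule
_COMPLEXITY: dict[str, Callable[[dict], tuple]] = {
    "gnb": lambda p: (-p.get("var_smoothing", 1e-9),),
    "logreg_l1": lambda p: (p.get("C", 1.0),),
    "svm_poly": lambda p: (p.get("degree", 3), p.get("C", 1.0)),
    "svm_rbf": lambda p: (p.get("C", 1.0), p.get("gamma", 1.0)
                          if isinstance(p.get("gamma", "scale"), (int, float)) else 0.0),
    "random_forest": lambda p: (p.get("max_depth") or 99, p.get("n_estimators", 100)),
    "gradient_boosted_trees": lambda p: (
        p.get("max_depth", 6), p.get("n_estimators", 100),
    ),
}

DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "gnb": {"var_smoothing": (1e-9, 1e-7)},
    "logreg_l1": {"C": (0.1, 1.0, 10.0)},
    "svm_poly": {"C": (0.1, 1.0, 10.0), "degree": (2, 3)},
    "svm_rbf": {"C": (0.1, 1.0, 10.0), "gamma": ("scale",)},
    "random_forest": {"n_estimators": (100, 200), "max_depth": (3, 5, None)},
    "gradient_boosted_trees": {
        "n_estimators": (100, 200), "max_depth": (2, 3), "learning_rate": (0.1,),
    },
}


@dataclass
class ClassifierSpec:
    """One classifier kind plus its hyperparameter grid."""

    kind: str
    grid: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not self.grid:
            self.grid = dict(DEFAULT_GRIDS[self.kind])

    def candidates(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in product(*(self.grid[k] for k in keys))]


def select_one_sd(
    means: Sequence[float], sds: Sequence[float], complexities: Sequence[tuple]
) -> int:
    """Index of the simplest candidate within one sd of the best mean.

    ``sds`` are the fold-score standard deviations; the tolerance band is
    the best candidate's own sd.
    """
    means = np.asarray(means, dtype=float)
    if len(means) == 0:
        raise ValueError("empty candidate grid")
    best = int(np.argmax(means))
    threshold = means[best] - float(sds[best])
    eligible = [i for i in range(len(means)) if means[i] >= threshold]
    return min(eligible, key=lambda i: (tuple(complexities[i]), -means[i]))


def grid_search_1sd(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
):
    """Grid search under the one-sd rule in stratified k-fold CV (AUC).

    Returns the refitted winning model and a CV report DataFrame.
    """
    labels = np.asarray(labels)
    candidates = spec.candidates()
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    x = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    n_folds = min(folds, int(np.bincount(labels).min()))
    if n_folds < 2:
        raise ValueError("need at least 2 rows per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(x, labels))

    means, sds = [], []
    for params in candidates:
        scores = []
        for tr, te in splits:
            model = _make_estimator(spec.kind, params, spec.seed)
            model.fit(x[tr], labels[tr])
            prob = model.predict_proba(x[te])[:, 1]
            scores.append(roc_auc_score(labels[te], prob))
        means.append(float(np.mean(scores)))
        sds.append(float(np.std(scores)))

    complexities = [_COMPLEXITY[spec.kind](p) for p in candidates]
    chosen = select_one_sd(means, sds, complexities)
    model = _make_estimator(spec.kind, candidates[chosen], spec.seed)
    model.fit(x, labels)
    report = pd.DataFrame(
        {
            "params": [repr(p) for p in candidates],
            "cv_auc_mean": means,
            "cv_auc_sd": sds,
            "selected": [i == chosen for i in range(len(candidates))],
        }
    )
    return model, report


def soft_vote(probs: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Weighted average of class-1 probabilities: sum w_k p_k / sum w_k."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if weights.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    probs = [np.asarray(p, dtype=float) for p in probs]
    if len(probs) != len(weights):
        raise ValueError("one probability vector per weight required")
    return sum(w * p for w, p in zip(weights, probs)) / weights.sum()


@dataclass
class MetricsReport:
    acc: float
    auc: float
    sensitivity: dict[int, float]
    specificity: dict[int, float]
    roc_points: pd.DataFrame
    calibration_bins: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
        }


def evaluate(
    prob_scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """ACC/AUC/per-class sensitivity+specificity, ROC and calibration points.

    AUC uses the trapezoidal ROC with half-credit tie handling (equivalent
    to the Mann-Whitney U statistic).  Per-class sensitivity of class 0
    equals specificity of class 1 by definition.
    """
    scores = np.asarray(prob_scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    acc = float((pred == labels).mean())
    auc = float(roc_auc_score(labels, scores))
    sens, spec = {}, {}
    for cls in (0, 1):
        is_cls = labels == cls
        pred_cls = pred == cls
        sens[cls] = float(pred_cls[is_cls].mean())
        spec[cls] = float((~pred_cls[~is_cls]).mean())
    fpr, tpr, thr = roc_curve(labels, scores)
    frac_pos, mean_pred = calibration_curve(labels, scores, n_bins=10, strategy="uniform")
    return MetricsReport(
        acc=acc,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        calibration_bins=pd.DataFrame(
            {"mean_predicted": mean_pred, "fraction_positive": frac_pos}
        ),
    )


@dataclass
class RSVModel:
    """Weighted soft vote of the two best base classifiers."""

    base_kinds: tuple[str, str]
    base_models: tuple
    weights: tuple[float, float]
    cv_auc: dict[str, float] = field(default_factory=dict)

    def predict_proba(self, table) -> np.ndarray:
        x = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
        probs = [m.predict_proba(x)[:, 1] for m in self.base_models]
        return self.vote(probs)

    def vote(self, probs: Sequence[np.ndarray]) -> np.ndarray:
        return soft_vote(probs, self.weights)


def build_rsv(
    table: pd.DataFrame,
    labels: np.ndarray,
    candidate_specs: Sequence[ClassifierSpec] | None = None,
    weight_grid: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_GRID,
    folds: int = 10,
    seed: int = 0,
) -> RSVModel:
    """Train the RSV ensemble: rank candidates by CV AUC, keep the top two,
    and choose the vote weights by out-of-fold AUC over the weight grid.

    Ranking ties prefer the {random_forest, svm_rbf} pair.  The first base
    model is the better-ranked one, so a (2, 1) weight favors it.
    """
    candidate_specs = list(
        candidate_specs
        or [ClassifierSpec(kind=k, seed=seed) for k in CLASSIFIER_KINDS]
    )
    if len(candidate_specs) < 2:
        raise ValueError("need at least two candidate classifiers")
    labels = np.asarray(labels)
    x = table.to_numpy()
    n_folds = min(folds, int(np.bincount(labels).min()))
    cv = StratifiedKFold(n_splits=max(n_folds, 2), shuffle=True, random_state=seed)
    splits = list(cv.split(x, labels))

    fitted: dict[str, object] = {}
    oof: dict[str, np.ndarray] = {}
    aucs: dict[str, float] = {}
    for spec in candidate_specs:
        model, _ = grid_search_1sd(spec, table, labels, folds=folds, seed=seed)
        fitted[spec.kind] = model
        probs = np.zeros(len(labels))
        for tr, te in splits:
            # refit the winning hyperparameters per fold
            fold_model = _clone_with_params(spec, model)
            fold_model.fit(x[tr], labels[tr])
            probs[te] = fold_model.predict_proba(x[te])[:, 1]
        oof[spec.kind] = probs
        aucs[spec.kind] = float(roc_auc_score(labels, probs))

    preferred = {"random_forest": 1, "svm_rbf": 1}
    ranked = sorted(
        aucs, key=lambda k: (-round(aucs[k], 12), -preferred.get(k, 0), k)
    )
    top2 = tuple(ranked[:2])

    best_w, best_auc = None, -np.inf
    for w in weight_grid:
        vote = soft_vote([oof[top2[0]], oof[top2[1]]], w)
        auc = roc_auc_score(labels, vote)
        if auc > best_auc + 1e-12:
            best_w, best_auc = tuple(float(v) for v in w), float(auc)
    return RSVModel(
        base_kinds=top2,
        base_models=(fitted[top2[0]], fitted[top2[1]]),
        weights=best_w,
        cv_auc=aucs,
    )


def _clone_with_params(spec: ClassifierSpec, fitted_model):
    """Fresh estimator of the same kind carrying the tuned grid parameters."""
    params = {k: fitted_model.get_params()[k] for k in DEFAULT_GRIDS[spec.kind]
              if k in fitted_model.get_params()}
    # grid keys not in this spec's custom grid still exist as estimator params
    for k in spec.grid:
        if k in fitted_model.get_params():
            params[k] = fitted_model.get_params()[k]
    return _make_estimator(spec.kind, params, spec.seed)
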
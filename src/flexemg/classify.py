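"""Classifier training/evaluation and confusion-matrix metrics.

Three classifier families are compared on ratio feature tables: a
gradient-boosted decision tree ensemble, an RBF-kernel support vector
machine, and k-nearest neighbours. Evaluation follows the study protocol:
a random 80/20 train/test split (stratified by default) and stratified
5-fold cross-validation; within each training fold a small grid search
picks hyperparameters by inner-fold accuracy.

The positive class is **immobilization** (label 1) and the negative class
nerve injury (label 0), so

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)

are computed by exact rational arithmetic from the confusion counts; a
metric whose denominator is zero is reported as ``None`` (undefined), never
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import DEFAULT_CLASSIFIER_FEATURES

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "ClassifierSpec",
    "CVResult",
    "split_dataset",
    "compute_metrics",
    "fit_predict",
    "run_cv",
    "DEFAULT_GRIDS",
]

KINDS = ("gbdt", "svm_rbf", "knn")

# Hyperparameter grids, searched by inner-fold accuracy. The svm gamma
# values are the 'scale' heuristic (1 / n_features on standardized data,
# = 0.25 for the default 4-feature set) times {0.5, 1, 2}.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbdt": {
        "max_depth": [2, 3, 4],
        "n_estimators": [100, 300],
        "learning_rate": [0.1],
    },
    "svm_rbf": {"C": [1.0, 10.0, 100.0], "gamma": [0.125, 0.25, 0.5]},
    "knn": {"n_neighbors": [3, 5, 7, 9]},
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with positive = immobilization."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionMatrix(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy / specificity / sensitivity as fractions in [0, 1].

    A field is ``None`` when its denominator is zero (undefined).
    """

    accuracy: float | None
    specificity: float | None
    sensitivity: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in self.__dict__.items()
        }


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Exact rational evaluation of the three summary statistics."""

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else float(Fraction(num, den))

    return Metrics(
        accuracy=frac(cm.tp + cm.tn, cm.total),
        specificity=frac(cm.tn, cm.tn + cm.fp),
        sensitivity=frac(cm.tp, cm.tp + cm.fn),
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus its hyperparameter grid and seed."""

    kind: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; one of {KINDS}")
        if self.grid is not None and not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def effective_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.kind]


def _estimator(kind: str, seed: int):
    if kind == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf")
    return KNeighborsClassifier()


def split_dataset(
    table: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row-level train/test split, stratified by label by default."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present before splitting")
    strat = y if stratified else None
    train, test = train_test_split(
        table, train_size=train_frac, random_state=seed, stratify=strat
    )
    if len(train) == 0 or len(test) == 0:
        raise ValueError("split produced an empty side")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _fit(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: int = 3,
):
    """Standardize-then-classify pipeline, grid-searched when meaningful."""
    pipe = Pipeline(
        [("scale", StandardScaler()), ("clf", _estimator(spec.kind, spec.seed))]
    )
    grid = {f"clf__{k}": v for k, v in spec.effective_grid.items()}
    n_combos = int(np.prod([len(v) for v in grid.values()]))
    min_class = int(np.bincount(y.astype(int)).min())
    if n_combos > 1 and min_class >= inner_folds:
        search = GridSearchCV(
            pipe,
            grid,
            scoring="accuracy",
            cv=StratifiedKFold(inner_folds, shuffle=True, random_state=spec.seed),
            refit=True,
        )
        search.fit(X, y)
        return search.best_estimator_, search.best_params_
    pipe.set_params(**{k: v[0] for k, v in grid.items()})
    pipe.fit(X, y)
    return pipe, {k: v[0] for k, v in grid.items()}


def _design(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    return X, y


def fit_predict(
    spec: ClassifierSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    *,
    features: tuple[str, ...] = DEFAULT_CLASSIFIER_FEATURES,
) -> ConfusionMatrix:
    """Fit on *train*, predict *test*, return the confusion counts.

    Features are standardized with training-fold statistics only (no
    leakage: the test rows and their labels never enter the fit).
    """
    X_tr, y_tr = _design(train, features)
    X_te, y_te = _design(test, features)
    model, _ = _fit(spec, X_tr, y_tr)
    y_pred = model.predict(X_te)
    return ConfusionMatrix.from_labels(y_te, y_pred)


@dataclass
class CVResult:
    """Per-fold metrics and their mean +- SD."""

    spec: ClassifierSpec
    fold_metrics: list[Metrics]
    fold_cms: list[ConfusionMatrix]
    chosen_params: list[dict]
    mean: Metrics = field(init=False)
    sd: Metrics = field(init=False)

    def __post_init__(self) -> None:
        def agg(name, fn):
            vals = [getattr(m, name) for m in self.fold_metrics]
            vals = [v for v in vals if v is not None]
            return float(fn(vals)) if vals else None

        self.mean = Metrics(*(agg(n, np.mean) for n in
                              ("accuracy", "specificity", "sensitivity")))
        self.sd = Metrics(*(agg(n, lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0)
                            for n in ("accuracy", "specificity", "sensitivity")))


def run_cv(
    table: pd.DataFrame,
    k_folds: int = 5,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    *,
    features: tuple[str, ...] = DEFAULT_CLASSIFIER_FEATURES,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with inner grid search.

    The seed controls both fold assignment and any classifier randomness.
    Passing ``groups`` (e.g. subject ids) switches to subject-wise folds so
    that windows of one subject never straddle a fold boundary. Raises on
    degenerate folds (a class absent from a training fold).
    """
    spec = spec or ClassifierSpec("gbdt")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X, y = _design(table, features)
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < k_folds:
        raise ValueError("each class needs at least k_folds rows")
    if groups is not None:
        skf = StratifiedGroupKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = skf.split(X, y, groups=np.asarray(groups))
    else:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = skf.split(X, y)
    fold_metrics, fold_cms, chosen = [], [], []
    for tr_idx, te_idx in splits:
        if len(np.unique(y[tr_idx])) < 2:
            raise ValueError("degenerate single-class training fold")
        model, params = _fit(spec, X[tr_idx], y[tr_idx])
        y_pred = model.predict(X[te_idx])
        cm = ConfusionMatrix.from_labels(y[te_idx], y_pred)
        fold_cms.append(cm)
        fold_metrics.append(compute_metrics(cm))
        chosen.append(params)
    return CVResult(spec=spec, fold_metrics=fold_metrics,
                    fold_cms=fold_cms, chosen_params=chosen)
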
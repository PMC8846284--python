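"""Linear SVM diagnosis: binary and multiclass, LOOCV, training strategies.

The working classifier is a linear SVM with squared hinge loss in a
one-vs-rest multiclass scheme.  Features are standardized (zero mean, unit
SD) with statistics computed on the training rows only, and the cost
parameter C is chosen by inner stratified cross-validation over a
log-spaced grid.  Logistic-regression and random-forest backends sit
behind the same interface for comparison runs.

Evaluation is leave-one-out cross-validation (LOOCV) unless a strategy
dictates a holdout split.  The four early/advanced-stage training
strategies:

1. train on all advanced-stage (AS) patients plus the other early-stage
   (ES) patients, LOOCV over ES;
2. LOOCV within ES only;
3. train on all AS, test all ES (holdout);
4. train on an AS subsample of ES size (seeded), test all ES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import DIAGNOSES
from .evaluation import ConfusionMatrix, auc_rank

__all__ = [
    "ClassifierConfig",
    "StrategySpec",
    "ClassificationResult",
    "feature_matrix",
    "fit",
    "loocv",
    "run_strategy",
    "binary_tasks",
]


@dataclass
class ClassifierConfig:
    """Configuration of the diagnostic classifier."""

    backend: str = "svm"  # svm | logreg | rf
    c_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-3, 4))
    inner_cv_folds: int = 5
    class_weight: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid:
            raise ValueError("c_grid must be nonempty")


def _estimator(config: ClassifierConfig, c: float):
    if config.backend == "svm":
        return LinearSVC(
            C=c,
            loss="squared_hinge",
            dual=False,
            class_weight=config.class_weight,
            random_state=config.seed,
        )
    if config.backend == "logreg":
        return LogisticRegression(
            C=c, max_iter=2000, class_weight=config.class_weight,
            random_state=config.seed,
        )
    if config.backend == "rf":
        return RandomForestClassifier(
            n_estimators=200, class_weight=config.class_weight,
            random_state=config.seed,
        )
    raise ValueError(f"unknown backend {config.backend!r}")


def feature_matrix(
    table: pd.DataFrame,
    feature_set: str = "striatum+midbrain",
    include_asymmetry: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Split a cohort feature table into (X indexed by subject, y groups)."""
    from .features import feature_columns

    cols = [f"sor_{c}" for c in feature_columns(feature_set)]
    if include_asymmetry:
        cols += [c for c in table.columns if c.startswith("ai_")]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    X = table.set_index("subject_id")[cols].astype(float)
    y = table.set_index("subject_id")["group"]
    return X, y


def fit(X: pd.DataFrame, y, config: ClassifierConfig | None = None):
    """Fit the configured classifier with inner-CV choice of C.

    Standardization statistics come from the training rows only (the
    scaler sits inside the pipeline, hence inside every inner fold).
    """
    config = config or ClassifierConfig()
    X = pd.DataFrame(X)
    y = pd.Series(y, index=X.index)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("training set contains a single class")

    pipe = Pipeline(
        [("scale", StandardScaler()), ("clf", _estimator(config, 1.0))]
    )
    if len(config.c_grid) == 1 or config.backend == "rf":
        if config.backend != "rf":
            pipe.set_params(clf__C=float(config.c_grid[0]))
        pipe.fit(X.values, y.values)
        return pipe

    min_class = int(y.value_counts().min())
    folds = max(2, min(config.inner_cv_folds, min_class))
    gs = GridSearchCV(
        pipe,
        {"clf__C": list(config.c_grid)},
        cv=StratifiedKFold(folds, shuffle=True, random_state=config.seed),
        n_jobs=None,
    )
    gs.fit(X.values, y.values)
    return gs.best_estimator_


def _scores(model, X: np.ndarray, classes: list[str]) -> np.ndarray:
    """Per-class decision scores as an (n, k) array in ``classes`` order."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        s = model.decision_function(X)
    else:
        s = model.predict_proba(X)
    s = np.asarray(s, dtype=float)
    model_classes = list(clf.classes_)
    if s.ndim == 1:
        # binary decision_function: one column, the score of classes_[1]
        s = np.column_stack([-s, s])
    out = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        if c in model_classes:
            out[:, j] = s[:, model_classes.index(c)]
        else:
            out[:, j] = -np.inf
    return out


@dataclass
class ClassificationResult:
    """Per-subject predictions with decision scores."""

    ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    scores: pd.DataFrame  # index = ids, columns = classes
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.y_true) == len(self.y_pred)):
            raise ValueError("ids / truth / predictions length mismatch")

    @property
    def accuracy(self) -> float:
        return float(
            np.mean([t == p for t, p in zip(self.y_true, self.y_pred)])
        )

    def confusion(self) -> ConfusionMatrix:
        classes = tuple(c for c in self.classes)
        return ConfusionMatrix.from_predictions(self.y_true, self.y_pred, classes)

    def correct(self) -> pd.Series:
        return pd.Series(
            [t == p for t, p in zip(self.y_true, self.y_pred)],
            index=self.ids,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.ids, "true": self.y_true, "predicted": self.y_pred}
        )
        for c in self.scores.columns:
            df[f"score_{c}"] = self.scores[c].values
        return df


def loocv(
    X: pd.DataFrame,
    y,
    config: ClassifierConfig | None = None,
    augment: tuple[pd.DataFrame, pd.Series] | None = None,
) -> ClassificationResult:
    """Leave-one-out cross-validation, optionally with a fixed augment pool.

    Every held-out subject is predicted by a model trained on all other
    rows plus the augment rows.  A held-out subject appearing in the
    augment pool is a leakage error.
    """
    config = config or ClassifierConfig()
    X = pd.DataFrame(X)
    y = pd.Series(y, index=X.index)
    if len(X) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if augment is not None:
        aug_X, aug_y = pd.DataFrame(augment[0]), pd.Series(augment[1])
        overlap = set(aug_X.index) & set(X.index)
        if overlap:
            raise ValueError(f"augment pool contains held-out subjects: {sorted(overlap)}")
    classes = sorted(set(y) | (set(augment[1]) if augment is not None else set()))

    ids, y_true, y_pred, rows = [], [], [], []
    for sid in X.index:
        tr_X = X.drop(index=sid)
        tr_y = y.drop(index=sid)
        if augment is not None:
            tr_X = pd.concat([tr_X, aug_X])
            tr_y = pd.concat([tr_y, aug_y])
        model = fit(tr_X, tr_y, config)
        s = _scores(model, X.loc[[sid]].values, classes)[0]
        pred = model.predict(X.loc[[sid]].values)[0]
        ids.append(sid)
        y_true.append(y.loc[sid])
        y_pred.append(pred)
        rows.append(s)
    scores = pd.DataFrame(rows, index=ids, columns=classes)
    return ClassificationResult(ids, y_true, y_pred, scores, tuple(classes))


def _holdout(
    train_X, train_y, test_X, test_y, config: ClassifierConfig
) -> ClassificationResult:
    classes = sorted(set(train_y))
    model = fit(train_X, train_y, config)
    preds = model.predict(test_X.values)
    s = _scores(model, test_X.values, classes)
    scores = pd.DataFrame(s, index=test_X.index, columns=classes)
    return ClassificationResult(
        list(test_X.index), list(test_y), list(preds), scores, tuple(classes)
    )


@dataclass
class StrategySpec:
    """One of the four early/advanced-stage training strategies."""

    id: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.id not in (1, 2, 3, 4):
            raise ValueError("strategy id must be 1..4")


def run_strategy(
    table: pd.DataFrame,
    strategy: StrategySpec | int,
    config: ClassifierConfig | None = None,
    feature_set: str = "striatum+midbrain",
) -> ClassificationResult:
    """Run one ES/AS training strategy over a patient cohort table."""
    if isinstance(strategy, int):
        strategy = StrategySpec(strategy)
    config = config or ClassifierConfig()

    patients = table[table["group"].isin(DIAGNOSES)]
    if "stage" not in patients.columns or patients["stage"].isin(["NA", ""]).any():
        raise ValueError("stage labels are required for training strategies")
    X, y = feature_matrix(patients, feature_set)
    stage = patients.set_index("subject_id")["stage"]
    es_idx = stage[stage == "ES"].index
    as_idx = stage[stage == "AS"].index
    if len(es_idx) < 3 or len(as_idx) < 1:
        raise ValueError("insufficient ES/AS pool sizes for the strategies")

    if strategy.id == 1:
        return loocv(
            X.loc[es_idx], y.loc[es_idx], config,
            augment=(X.loc[as_idx], y.loc[as_idx]),
        )
    if strategy.id == 2:
        return loocv(X.loc[es_idx], y.loc[es_idx], config)
    if strategy.id == 3:
        return _holdout(X.loc[as_idx], y.loc[as_idx], X.loc[es_idx], y.loc[es_idx], config)
    # strategy 4: AS training pool subsampled to the ES size, seeded
    n = len(es_idx)
    if n > len(as_idx):
        raise ValueError("AS pool smaller than requested subsample size")
    rng = np.random.default_rng(config.seed)
    keep = as_idx[np.sort(rng.choice(len(as_idx), size=n, replace=False))]
    return _holdout(X.loc[keep], y.loc[keep], X.loc[es_idx], y.loc[es_idx], config)


def binary_tasks(
    X: pd.DataFrame, y, config: ClassifierConfig | None = None
) -> dict[str, tuple[ClassificationResult, float]]:
    """One-vs-rest LOOCV per disease, with rank-statistic AUC over the
    held-out decision scores."""
    config = config or ClassifierConfig()
    y = pd.Series(y, index=pd.DataFrame(X).index)
    if set(DIAGNOSES) - set(y.unique()):
        raise ValueError("all three diagnostic classes must be present")
    out = {}
    for disease in DIAGNOSES:
        yb = y.map(lambda g: disease if g == disease else "rest")
        res = loocv(X, yb, config)
        scores = res.scores[disease].values
        labels = np.array([t == disease for t in res.y_true])
        out[disease] = (res, auc_rank(scores, labels))
    return out
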
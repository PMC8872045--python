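"""Grouped cross-validated classification and the five evaluation metrics.

Three classifiers — gradient-boosted trees (XGBoost), an RBF-kernel support
vector classifier and L2 logistic regression — are benchmarked over all six
binary and four multiclass condition contrasts. Cross-validation folds
partition PARTICIPANTS: every row of a participant lands in the same fold, so
a subject never contributes to both training and testing of a fold.

Precision, recall, F1 and accuracy are computed directly from confusion
counts (precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
accuracy = (TP+TN)/total); the ROC curve is built by an explicit threshold
sweep of TPR = TP/(TP+FN) against FPR = FP/(FP+TN) and AUROC by the
trapezoidal rule. Multiclass values are unweighted macro-averages of
per-class one-vs-rest reductions. The SVC and logistic models see
within-fold standardized features (z-scored on the training fold only);
tree boosting is scale-free and runs on raw features.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import CONDITIONS
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
)
from .selection import SelectionResult

#: Default hyperparameters for the three classifiers.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "xgboost": {"eta": 0.3, "gamma": 0, "max_depth": 6, "min_child_weight": 1},
    "svc": {"kernel": "rbf", "gamma": "auto"},
    "logreg": {"penalty": "l2", "solver": "newton-cg"},
}

CLASSIFIER_KINDS = ("xgboost", "svc", "logreg")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise InvalidParameterError(f"unknown classifier kind {self.kind!r}")
        merged = {**DEFAULT_HYPERPARAMETERS[self.kind], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)


def default_specs() -> list[ClassifierSpec]:
    return [ClassifierSpec(kind) for kind in CLASSIFIER_KINDS]


@dataclass(frozen=True)
class Dataset:
    """Rows for one class contrast: selected features + labels + participant groups."""

    X: pd.DataFrame
    y: np.ndarray  # condition labels (strings)
    groups: np.ndarray  # participant ids, aligned with rows
    class_condition: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> tuple[str, ...]:
        """Contrast classes in canonical condition order."""
        return tuple(c for c in CONDITIONS if c in self.class_condition)


def assemble_dataset(
    feature_table: pd.DataFrame,
    selection: SelectionResult | list[str] | tuple[str, ...],
    class_condition,
) -> Dataset:
    """Filter rows to the contrast's conditions and columns to the selected features."""
    selected = (
        list(selection.selected)
        if isinstance(selection, SelectionResult)
        else list(selection)
    )
    classes = tuple(c for c in CONDITIONS if c in set(class_condition))
    if len(classes) < 2:
        raise InsufficientDataError("class_condition needs >= 2 known conditions")
    missing = [c for c in selected if c not in feature_table.columns]
    if missing:
        raise InvalidParameterError(f"feature table lacks selected columns: {missing}")
    sub = feature_table[feature_table["condition"].isin(classes)].copy()
    counts = sub["condition"].value_counts()
    thin = [c for c in classes if counts.get(c, 0) < 2]
    if thin:
        raise InsufficientDataError(f"fewer than 2 rows for condition(s): {thin}")
    order = {c: i for i, c in enumerate(CONDITIONS)}
    sub = sub.sort_values(
        ["participant_id", "condition"],
        key=lambda s: s.map(order) if s.name == "condition" else s,
    ).reset_index(drop=True)
    return Dataset(
        X=sub[selected],
        y=sub["condition"].to_numpy(),
        groups=sub["participant_id"].to_numpy(),
        class_condition=classes,
    )


# ---------------------------------------------------------------------------
# metrics from confusion counts


def confusion_matrix_counts(y_true, y_pred, classes) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def binary_counts(cm: np.ndarray, positive_index: int) -> tuple[int, int, int, int]:
    """One-vs-rest reduction of a KxK matrix to (TP, FP, TN, FN)."""
    k = positive_index
    tp = int(cm[k, k])
    fp = int(cm[:, k].sum() - cm[k, k])
    fn = int(cm[k, :].sum() - cm[k, k])
    tn = int(cm.sum() - tp - fp - fn)
    return tp, fp, tn, fn


def _prf_accuracy(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = np.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


def compute_metrics(cm: np.ndarray) -> dict[str, float]:
    """Precision, recall, F1, accuracy from a confusion matrix.

    Binary (2x2, class order canonical): the later condition is positive.
    Multiclass: unweighted macro-average of one-vs-rest values; classes whose
    value is undefined (e.g. never predicted -> precision 0/0) are excluded
    from that metric's mean with a warning.
    """
    cm = np.asarray(cm)
    if cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise InvalidParameterError("confusion matrix must be KxK with K >= 2")
    if cm.shape[0] == 2:
        return _prf_accuracy(*binary_counts(cm, positive_index=1))
    per_class = [_prf_accuracy(*binary_counts(cm, k)) for k in range(cm.shape[0])]
    out: dict[str, float] = {}
    for key in ("precision", "recall", "f1"):
        vals = np.array([m[key] for m in per_class])
        if np.isnan(vals).any():
            warnings.warn(
                f"{int(np.isnan(vals).sum())} class(es) with undefined {key} "
                "excluded from macro mean",
                stacklevel=2,
            )
        out[key] = float(np.nanmean(vals))
    out["accuracy"] = float(np.trace(cm) / cm.sum())
    return out


def compute_auroc(scores, labels) -> tuple[float, np.ndarray]:
    """AUROC and ROC points via an explicit threshold sweep.

    ``labels`` are booleans (True = positive); ``scores`` higher = more
    positive. Tied scores cross their threshold simultaneously, which makes
    the trapezoidal area equal to the Mann-Whitney statistic with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("AUROC needs >= 1 positive and >= 1 negative")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # all ties cross together
            tp += int(lab[j])
            fp += int(~lab[j])
            j += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    points = np.column_stack([fpr, tpr])
    auroc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return auroc, points


def macro_ovr_auroc(proba: np.ndarray, y_true, classes) -> float:
    """Unweighted one-vs-rest macro AUROC; classes absent from y_true are skipped."""
    vals = []
    for k, c in enumerate(classes):
        pos = np.asarray(y_true) == c
        if pos.all() or not pos.any():
            continue
        vals.append(compute_auroc(proba[:, k], pos)[0])
    if not vals:
        raise InsufficientDataError("no class with both positives and negatives")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# classifiers and grouped CV


def build_estimator(spec: ClassifierSpec, seed: int):
    """Instantiate one classifier; SVC/logreg get train-fold standardization."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    hp = spec.hyperparameters
    if spec.kind == "xgboost":
        return XGBClassifier(
            learning_rate=hp["eta"],
            gamma=hp["gamma"],
            max_depth=hp["max_depth"],
            min_child_weight=hp["min_child_weight"],
            n_estimators=100,
            tree_method="exact",  # exact greedy splits; datasets are tiny
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if spec.kind == "svc":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            svc = SVC(
                kernel=hp["kernel"],
                gamma=hp["gamma"],
                probability=True,  # ROC needs class-probability scores
                random_state=seed,
            )
        return make_pipeline(StandardScaler(), svc)
    if hp["penalty"] != "l2":
        raise InvalidParameterError("logreg supports only the L2 penalty")
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(solver=hp["solver"], max_iter=2000),  # L2 by default
    )


def participant_folds(
    groups: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded partition of participants into n_folds groups of near-equal size."""
    participants = np.array(sorted(set(groups)))
    if len(participants) < n_folds:
        raise InsufficientDataError(
            f"{len(participants)} participants cannot form {n_folds} grouped folds"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(participants)
    return [np.array(sorted(chunk)) for chunk in np.array_split(participants, n_folds)]


@dataclass
class EvalCell:
    """One (contrast x classifier) result."""

    class_condition: tuple[str, ...]
    classifier: str
    fold_metrics: list[dict[str, float]]
    metrics: dict[str, float]  # fold-averaged
    confusion: np.ndarray  # summed over folds
    roc_points: np.ndarray  # pooled held-out predictions
    importance: list[tuple[str, float]] | None  # xgboost only, top-5 normalized
    n_folds_used: int
    n_folds_skipped: int

    def to_dict(self) -> dict:
        return {
            "condition": " vs ".join(self.class_condition),
            "classifier": self.classifier,
            "metrics": self.metrics,
            "fold_metrics": self.fold_metrics,
            "confusion": self.confusion.tolist(),
            "roc_points": self.roc_points.tolist(),
            "importance": self.importance,
            "n_folds_used": self.n_folds_used,
            "n_folds_skipped": self.n_folds_skipped,
        }


def _xgb_total_gain(model, feature_names) -> dict[str, float]:
    booster = model.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    # xgboost keys are feature names when fitted from a DataFrame
    return {name: float(raw.get(name, 0.0)) for name in feature_names}


def feature_importance(
    fold_gains: list[dict[str, float]], top_n: int = 5
) -> list[tuple[str, float]]:
    """Average total-gain importances over folds, normalize to sum 1, take top_n."""
    if not fold_gains:
        return []
    names = list(fold_gains[0])
    mean_gain = {n: float(np.mean([g[n] for g in fold_gains])) for n in names}
    total = sum(mean_gain.values())
    if total == 0:
        warnings.warn("model made no splits; importance report empty", stacklevel=2)
        return []
    ranked = sorted(mean_gain.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(n, g / total) for n, g in ranked[:top_n] if g > 0]


def run_cv(
    dataset: Dataset,
    spec: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalCell:
    """Grouped n-fold cross-validation of one classifier on one contrast.

    Folds partition participants. A fold whose test split contains a single
    class is skipped (with a warning) when averaging. Deterministic given
    (data, spec, seed).
    """
    classes = dataset.classes
    folds = participant_folds(dataset.groups, n_folds, seed)
    class_to_int = {c: i for i, c in enumerate(classes)}
    y_int = np.array([class_to_int[c] for c in dataset.y])

    fold_metrics: list[dict[str, float]] = []
    fold_gains: list[dict[str, float]] = []
    total_cm = np.zeros((len(classes), len(classes)), dtype=int)
    pooled_scores: list[np.ndarray] = []
    pooled_true: list[np.ndarray] = []
    skipped = 0

    for fold_participants in folds:
        test_mask = np.isin(dataset.groups, fold_participants)
        train_mask = ~test_mask
        assert not np.any(test_mask & train_mask)  # leakage guard
        assert not set(dataset.groups[test_mask]) & set(dataset.groups[train_mask])
        if len(np.unique(y_int[test_mask])) < 2:
            warnings.warn(
                "test fold contains a single class; fold skipped", stacklevel=2
            )
            skipped += 1
            continue
        X_train = dataset.X[train_mask]
        X_test = dataset.X[test_mask]
        model = build_estimator(spec, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(X_train, y_int[train_mask])
        pred = model.predict(X_test)
        raw_proba = model.predict_proba(X_test)
        # predict_proba columns follow model.classes_; realign to contrast order
        # (a class absent from the training fold gets probability 0)
        col = {int(c): j for j, c in enumerate(model.classes_)}
        proba = np.zeros((raw_proba.shape[0], len(classes)))
        for i in range(len(classes)):
            if i in col:
                proba[:, i] = raw_proba[:, col[i]]

        cm = confusion_matrix_counts(y_int[test_mask], pred, list(range(len(classes))))
        total_cm += cm
        m = compute_metrics(cm)
        if len(classes) == 2:
            m["auroc"] = compute_auroc(proba[:, 1], y_int[test_mask] == 1)[0]
        else:
            m["auroc"] = macro_ovr_auroc(proba, y_int[test_mask], list(range(len(classes))))
        fold_metrics.append(m)
        pooled_scores.append(proba)
        pooled_true.append(y_int[test_mask])
        if spec.kind == "xgboost":
            fold_gains.append(_xgb_total_gain(model, list(dataset.X.columns)))

    if not fold_metrics:
        raise InsufficientDataError("every fold was degenerate; nothing evaluated")

    mean_metrics = {
        key: float(np.nanmean([m[key] for m in fold_metrics]))
        for key in ("precision", "recall", "f1", "accuracy", "auroc")
    }
    all_proba = np.vstack(pooled_scores)
    all_true = np.concatenate(pooled_true)
    if len(classes) == 2:
        _, roc_points = compute_auroc(all_proba[:, 1], all_true == 1)
    else:
        roc_points = _pooled_multiclass_roc(all_proba, all_true, len(classes))

    importance = (
        feature_importance(fold_gains) if spec.kind == "xgboost" else None
    )
    return EvalCell(
        class_condition=classes,
        classifier=spec.kind,
        fold_metrics=fold_metrics,
        metrics=mean_metrics,
        confusion=total_cm,
        roc_points=roc_points,
        importance=importance,
        n_folds_used=len(fold_metrics),
        n_folds_skipped=skipped,
    )


def _pooled_multiclass_roc(proba: np.ndarray, y_true: np.ndarray, n_classes: int) -> np.ndarray:
    """Pooled one-vs-rest ROC of the first class with both outcomes (for plotting)."""
    for k in range(n_classes):
        pos = y_true == k
        if pos.any() and not pos.all():
            return compute_auroc(proba[:, k], pos)[1]
    return np.array([[0.0, 0.0], [1.0, 1.0]])


# ---------------------------------------------------------------------------
# full benchmark over all contrasts


def benchmark_contrasts() -> list[tuple[str, ...]]:
    """The 6 binary and 4 multiclass condition contrasts of the benchmark."""
    binary = [tuple(pair) for pair in itertools.combinations(CONDITIONS, 2)]
    multi = [
        ("baseline", "low_arousal", "high_arousal"),
        ("baseline", "low_arousal", "social_anxiety"),
        ("low_arousal", "high_arousal", "social_anxiety"),
        CONDITIONS,
    ]
    return binary + multi


@dataclass
class EvaluationReport:
    cells: dict[tuple[tuple[str, ...], str], EvalCell]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for (contrast, clf), cell in self.cells.items():
            rows.append(
                {
                    "condition": " vs ".join(contrast),
                    "classifier": clf,
                    **{k: round(v, 6) for k, v in cell.metrics.items()},
                }
            )
        return pd.DataFrame(rows)

    def importance_frame(self) -> pd.DataFrame:
        rows = []
        for (contrast, clf), cell in self.cells.items():
            if cell.importance is None:
                continue
            for rank, (name, score) in enumerate(cell.importance, start=1):
                rows.append(
                    {
                        "condition": " vs ".join(contrast),
                        "rank": rank,
                        "feature": name,
                        "score": round(score, 6),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps([cell.to_dict() for cell in self.cells.values()], indent=2)


def run_full_benchmark(
    feature_table: pd.DataFrame,
    selection: SelectionResult | list[str],
    seed: int = 0,
    specs: list[ClassifierSpec] | None = None,
    n_folds: int = 5,
) -> EvaluationReport:
    """Evaluate every contrast x classifier cell (10 x 3 = 30 in full)."""
    specs = specs or default_specs()
    cells: dict[tuple[tuple[str, ...], str], EvalCell] = {}
    for contrast in benchmark_contrasts():
        dataset = assemble_dataset(feature_table, selection, contrast)
        for spec in specs:
            try:
                cell = run_cv(dataset, spec, n_folds=n_folds, seed=seed)
            except InsufficientDataError as exc:
                raise InsufficientDataError(
                    f"contrast {contrast} / {spec.kind}: {exc}"
                ) from exc
            cells[(dataset.classes, spec.kind)] = cell
    return EvaluationReport(cells)
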
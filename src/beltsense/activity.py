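"""Random-forest recognition of seven daily activities from feature windows.

The recognizer consumes standardized 561-element feature vectors. Two
evaluation schemes are provided: stratified 10-fold cross-validation at the
window level (measuring pooled, within-population accuracy) and
leave-one-person-out cross-validation (measuring generalization to an
unseen wearer). In both, standardization parameters and the forest are fit
on the training folds only, so no test information leaks into the model.

Hyperparameters are a library-standard baseline — 100 trees, unlimited
depth, sqrt(p) features per split — recorded in the model metadata along
with the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from .features import (
    N_FEATURES,
    FeatureWindow,
    StandardizationParams,
    apply_standardizer,
    feature_names,
    fit_standardizer,
)

__all__ = [
    "ACTIVITY_CLASSES",
    "ModelConfig",
    "ActivityModel",
    "EvalReport",
    "train",
    "predict",
    "evaluate_kfold",
    "evaluate_lopo",
    "save_model",
    "load_model",
]

#: Closed set of recognizable activities.
ACTIVITY_CLASSES = (
    "lay_down",
    "sit",
    "stand",
    "walk",
    "walk_downstairs",
    "walk_upstairs",
    "run",
)


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters and the seed; all recorded in metadata."""

    n_estimators: int = 100
    max_depth: int | None = None
    max_features: str = "sqrt"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "max_features": self.max_features,
            "seed": self.seed,
        }


@dataclass
class ActivityModel:
    """A trained forest plus everything needed to apply it consistently."""

    forest: RandomForestClassifier
    standardizer: StandardizationParams
    classes: tuple[str, ...]
    config: ModelConfig
    feature_names: list[str] = field(default_factory=feature_names)


@dataclass(frozen=True)
class EvalReport:
    """Pooled cross-validation result.

    ``confusion`` is a true x predicted count matrix over ``classes``;
    per-class precision/recall/F1 plus weighted and macro aggregate F1;
    ``fold_of_window`` maps each evaluated window index to its test fold.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1_per_class: np.ndarray
    f1_weighted: float
    f1_macro: float
    fold_of_window: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "f1_weighted": self.f1_weighted,
            "f1_macro": self.f1_macro,
        }


def _check_windows(windows: list[FeatureWindow], need_labels: bool = True) -> None:
    for w in windows:
        if w.features.shape != (N_FEATURES,):
            raise ValueError(f"expected feature vectors of length {N_FEATURES}")
        if need_labels and w.label is None:
            raise ValueError("all windows must carry an activity label")


def train(windows: list[FeatureWindow], config: ModelConfig = ModelConfig()) -> ActivityModel:
    """Fit the standardizer and forest on labeled training windows."""
    _check_windows(windows)
    labels = sorted({w.label for w in windows})
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 classes")
    unknown = set(labels) - set(ACTIVITY_CLASSES)
    if unknown:
        raise ValueError(f"unknown activity labels: {sorted(unknown)}")
    params = fit_standardizer(windows)
    X = np.stack([apply_standardizer(params, w).features for w in windows])
    y = np.asarray([w.label for w in windows])
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ActivityModel(
        forest=forest,
        standardizer=params,
        classes=tuple(labels),
        config=config,
    )


def predict(model: ActivityModel, windows: list[FeatureWindow]) -> list[str]:
    """One activity label per window, using the frozen train-time standardizer."""
    if not windows:
        return []
    _check_windows(windows, need_labels=False)
    X = np.stack([apply_standardizer(model.standardizer, w).features for w in windows])
    if not np.all(np.isfinite(X)):
        raise ValueError("windows contain non-finite features after standardization")
    return list(model.forest.predict(X))


def _report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: tuple[str, ...],
    fold_of_window: np.ndarray,
) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    return EvalReport(
        classes=classes,
        confusion=cm,
        precision=prec,
        recall=rec,
        f1_per_class=f1,
        f1_weighted=float(
            f1_score(y_true, y_pred, labels=list(classes), average="weighted", zero_division=0)
        ),
        f1_macro=float(
            f1_score(y_true, y_pred, labels=list(classes), average="macro", zero_division=0)
        ),
        fold_of_window=fold_of_window,
    )


def _cross_validate(
    windows: list[FeatureWindow],
    splits,
    config: ModelConfig,
    classes: tuple[str, ...],
) -> tuple[EvalReport, np.ndarray]:
    y = np.asarray([w.label for w in windows])
    y_pred = np.empty(len(windows), dtype=object)
    fold_of_window = np.full(len(windows), -1)
    for fold, (train_idx, test_idx) in enumerate(splits):
        assert not set(train_idx) & set(test_idx), "fold bookkeeping violated"
        model = train([windows[i] for i in train_idx], config)
        preds = predict(model, [windows[i] for i in test_idx])
        for i, p in zip(test_idx, preds):
            y_pred[i] = p
        fold_of_window[test_idx] = fold
    assert (fold_of_window >= 0).all(), "every window must be tested exactly once"
    return _report(y, y_pred, classes, fold_of_window), y_pred


def evaluate_kfold(
    windows: list[FeatureWindow],
    k: int = 10,
    config: ModelConfig = ModelConfig(),
) -> EvalReport:
    """Stratified k-fold CV at the window level, folds seeded from config.

    Every class needs at least ``k`` windows; standardization and the
    forest are re-fit per fold on training windows only.
    """
    _check_windows(windows)
    y = np.asarray([w.label for w in windows])
    classes = tuple(sorted(set(y)))
    counts = {c: int((y == c).sum()) for c in classes}
    starving = [c for c, n in counts.items() if n < k]
    if starving:
        raise ValueError(
            f"cannot stratify {k} folds: classes with fewer than {k} windows: {starving}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    X_dummy = np.zeros((len(windows), 1))
    report, _ = _cross_validate(windows, skf.split(X_dummy, y), config, classes)
    return report


def evaluate_lopo(
    windows: list[FeatureWindow],
    config: ModelConfig = ModelConfig(),
    group_of_subject: dict[str, str] | None = None,
) -> EvalReport | tuple[EvalReport, dict[str, EvalReport]]:
    """Leave-one-person-out CV: one fold per subject id.

    With ``group_of_subject`` (e.g. a gender map) the pooled predictions
    are additionally re-aggregated per group and a dict of per-group
    reports is returned alongside the overall one.
    """
    _check_windows(windows)
    subjects = [w.subject for w in windows]
    if any(s is None for s in subjects):
        raise ValueError("all windows must carry a subject id for LOPO")
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("LOPO needs at least 2 subjects")
    y = np.asarray([w.label for w in windows])
    groups = np.asarray(subjects, dtype=object)
    classes = tuple(sorted(set(y)))
    logo = LeaveOneGroupOut()
    X_dummy = np.zeros((len(windows), 1))
    report, preds = _cross_validate(
        windows, logo.split(X_dummy, y, groups), config, classes
    )
    if group_of_subject is None:
        return report

    # re-slice the pooled LOPO predictions by the subject attribute
    per_group: dict[str, EvalReport] = {}
    masks = {
        g: np.asarray([group_of_subject.get(s) == g for s in subjects])
        for g in sorted(set(group_of_subject.values()))
    }
    for g, mask in masks.items():
        if mask.any():
            per_group[g] = _report(
                y[mask], preds[mask], classes, report.fold_of_window[mask]
            )
    return report, per_group


def save_model(model: ActivityModel, path) -> None:
    """Persist as a joblib archive with a JSON metadata header."""
    payload = {
        "schema": "beltsense-model/1",
        "metadata": json.dumps(
            {"classes": list(model.classes), "config": model.config.to_dict()}
        ),
        "forest": model.forest,
        "standardizer_location": model.standardizer.location,
        "standardizer_scale": model.standardizer.scale,
        "standardizer_degenerate": list(model.standardizer.degenerate),
        "feature_names": model.feature_names,
    }
    joblib.dump(payload, path)


def load_model(path) -> ActivityModel:
    payload = joblib.load(path)
    schema = payload.get("schema", "")
    if not schema.startswith("beltsense-model/"):
        raise ValueError(f"not a beltsense model archive: {path}")
    major = int(schema.split("/", 1)[1])
    if major > 1:
        raise ValueError(f"model schema {schema} newer than this reader (major 1)")
    meta = json.loads(payload["metadata"])
    return ActivityModel(
        forest=payload["forest"],
        standardizer=StandardizationParams(
            location=payload["standardizer_location"],
            scale=payload["standardizer_scale"],
            degenerate=tuple(payload["standardizer_degenerate"]),
        ),
        classes=tuple(meta["classes"]),
        config=ModelConfig(**meta["config"]),
        feature_names=list(payload["feature_names"]),
    )
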
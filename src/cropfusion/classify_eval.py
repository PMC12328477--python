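"""Classifier harness, dataset splitting, and confusion-matrix metrics.

Eight configurable backends mirror the comparison set of the method: a
dense neural network (ReLU hidden layers, softmax output), a 1-D
convolutional network over the 6-feature sequence, random forest, decision
tree, RBF-kernel SVM, LightGBM, XGBoost and CatBoost.  The gradient-
boosting backends and CatBoost are optional plug-ins behind a capability
check so the core package carries no heavyweight mandatory dependencies.

Evaluation is binary with wheat as the positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._conv1d import Conv1DClassifier
from .errors import CapabilityError, ValidationError
from .feature_fusion import FEATURE_ORDER, FeatureDataset
from .raster_model import LabelRaster

__all__ = [
    "BACKEND_NAMES",
    "SplitSpec",
    "ClassifierSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "TrainedModel",
    "split_dataset",
    "train_classifier",
    "confusion",
    "metrics",
    "evaluate",
    "window_size_sweep",
    "classification_map",
]

BACKEND_NAMES = (
    "DNN", "Conv1D", "RF", "DT", "SVM", "LightGBM", "XGBoost", "CatBoost",
)

#: Default hyperparameters per backend.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "DNN": {"hidden_layers": (128, 256, 128), "learning_rate": 0.0005,
            "epochs": 120},
    "Conv1D": {"filters": (64, 128), "kernel_size": 3,
               "learning_rate": 0.0005, "epochs": 120},
    "RF": {"n_trees": 200, "max_depth": 10},
    "DT": {"criterion": "gini", "max_depth": 8},
    "SVM": {"kernel": "rbf", "C": 0.5},
    "LightGBM": {"num_leaves": 40, "max_depth": 8},
    "XGBoost": {"learning_rate": 0.05, "max_depth": 6},
    "CatBoost": {"depth": 6, "learning_rate": 0.03, "l2_leaf_reg": 3.5},
}

#: Backends whose optimisation is scale-sensitive get a standardizer.
_SCALED_BACKENDS = {"DNN", "Conv1D", "SVM"}


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 80:10:10), seeded."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 1337
    stratified: bool = True

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValidationError("fractions must be three positive numbers")
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise ValidationError("fractions must sum to 1")


@dataclass(frozen=True)
class ClassifierSpec:
    """Backend name plus hyperparameter overrides."""

    name: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BACKEND_NAMES:
            raise ValidationError(
                f"unknown classifier {self.name!r}; expected one of {BACKEND_NAMES}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMS[self.name])
        unknown = set(self.hyperparams) - set(params)
        if unknown:
            raise ValidationError(
                f"{self.name}: unknown hyperparameters {sorted(unknown)}"
            )
        params.update(self.hyperparams)
        return params


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Partition sizes: round(fraction * n) for val/test, remainder to train."""
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError(f"dataset of {n} rows too small for the split")
    return n_train, n_val, n_test


def split_dataset(
    dataset: FeatureDataset, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureDataset, FeatureDataset, FeatureDataset]:
    """Disjoint, exhaustive train/validation/test partition.

    Sizes are ``round(fraction * n)`` with the remainder assigned to train;
    stratified by class when enabled; deterministic for a fixed seed.
    """
    from sklearn.model_selection import train_test_split

    n = len(dataset)
    if n == 0:
        raise ValidationError("dataset is empty")
    n_train, n_val, n_test = split_sizes(n, spec.fractions)
    idx = np.arange(n)
    y = dataset.y
    strat = y if spec.stratified else None
    try:
        rest, test_idx = train_test_split(
            idx, test_size=n_test, random_state=spec.seed, stratify=strat
        )
        strat_rest = y[rest] if spec.stratified else None
        train_idx, val_idx = train_test_split(
            rest, test_size=n_val, random_state=spec.seed + 1, stratify=strat_rest
        )
    except ValueError as exc:
        raise ValidationError(f"stratified split failed: {exc}") from exc

    def subset(sub: np.ndarray) -> FeatureDataset:
        return FeatureDataset(
            frame=dataset.frame.iloc[np.sort(sub)].reset_index(drop=True),
            interval=dataset.interval,
        )

    return subset(train_idx), subset(val_idx), subset(test_idx)


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


def _build_estimator(spec: ClassifierSpec, seed: int):
    p = spec.resolved()
    name = spec.name
    if name == "DNN":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=tuple(p["hidden_layers"]),
            activation="relu",
            solver="adam",
            learning_rate_init=p["learning_rate"],
            max_iter=int(p["epochs"]),
            random_state=seed,
        )
    if name == "Conv1D":
        return Conv1DClassifier(
            filters=tuple(p["filters"]),
            kernel_size=int(p["kernel_size"]),
            learning_rate=p["learning_rate"],
            epochs=int(p["epochs"]),
            random_state=seed,
        )
    if name == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=int(p["n_trees"]), max_depth=int(p["max_depth"]),
            random_state=seed,
        )
    if name == "DT":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(
            criterion=p["criterion"], max_depth=int(p["max_depth"]),
            random_state=seed,
        )
    if name == "SVM":
        from sklearn.svm import SVC

        return SVC(kernel=p["kernel"], C=p["C"], random_state=seed)
    if name == "LightGBM":
        try:
            from lightgbm import LGBMClassifier
        except ImportError as exc:
            raise CapabilityError(
                "LightGBM backend requires the 'lightgbm' package"
            ) from exc
        return LGBMClassifier(
            num_leaves=int(p["num_leaves"]), max_depth=int(p["max_depth"]),
            random_state=seed, verbose=-1,
        )
    if name == "XGBoost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:
            raise CapabilityError(
                "XGBoost backend requires the 'xgboost' package"
            ) from exc
        return XGBClassifier(
            learning_rate=p["learning_rate"], max_depth=int(p["max_depth"]),
            random_state=seed,
        )
    if name == "CatBoost":
        try:
            from catboost import CatBoostClassifier
        except ImportError as exc:
            raise CapabilityError(
                "CatBoost backend requires the 'catboost' package"
            ) from exc
        return CatBoostClassifier(
            depth=int(p["depth"]), learning_rate=p["learning_rate"],
            l2_leaf_reg=p["l2_leaf_reg"], random_seed=seed, verbose=False,
        )
    raise ValidationError(f"unknown classifier {name!r}")  # pragma: no cover


@dataclass
class TrainedModel:
    """Opaque predict-capable handle around a fitted backend."""

    spec: ClassifierSpec
    pipeline: object
    classes: np.ndarray
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*"
            )
            enc = self.pipeline.predict(np.asarray(X, dtype=float))
        return self.classes[np.asarray(enc, dtype=int)]


def train_classifier(
    spec: ClassifierSpec, train: FeatureDataset, seed: int = 1337
) -> TrainedModel:
    """Fit one backend on a feature dataset; training is seeded.

    Scale-sensitive backends (DNN, Conv1D, SVM) are wrapped with a
    standardizer.  Class labels are internally encoded to 0..K-1.
    """
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    y = train.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("training set must contain at least 2 classes")
    est = _build_estimator(spec, seed)
    steps = (
        [("scale", StandardScaler()), ("model", est)]
        if spec.name in _SCALED_BACKENDS
        else [("model", est)]
    )
    pipe = Pipeline(steps)
    y_enc = np.searchsorted(classes, y)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(train.X, y_enc)
    return TrainedModel(spec=spec, pipeline=pipe, classes=classes, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with a designated positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall / F1; NaN marks undefined ratios."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def as_percent(self) -> dict[str, float]:
        """Half-up integer percentages, NaN passed through."""
        out = {}
        for k, v in self.as_dict().items():
            out[k] = v if math.isnan(v) else math.copysign(
                math.floor(abs(v) * 100 + 0.5), v
            )
        return out


def confusion(
    pred: Sequence[int], truth: Sequence[int], positive: int = 1
) -> ConfusionMatrix:
    """Tally binary confusion counts; anything != positive is negative."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal length")
    pp = pred == positive
    tp_ = truth == positive
    return ConfusionMatrix(
        TP=int(np.sum(pp & tp_)),
        FP=int(np.sum(pp & ~tp_)),
        FN=int(np.sum(~pp & tp_)),
        TN=int(np.sum(~pp & ~tp_)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts."""
    if cm.total == 0:
        warnings.warn("empty confusion matrix; all metrics NaN")
        nan = float("nan")
        return MetricsReport(nan, nan, nan, nan)
    accuracy = (cm.TP + cm.TN) / cm.total
    precision = _ratio(cm.TP, cm.TP + cm.FP, "precision")
    recall = _ratio(cm.TP, cm.TP + cm.FN, "recall")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        if not (math.isnan(precision) or math.isnan(recall)):
            warnings.warn("F1 undefined (precision + recall = 0); reporting NaN")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy, precision, recall, f1)


def evaluate(
    model: TrainedModel, dataset: FeatureDataset, positive: int = 1
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Predict a dataset and report binary metrics (wheat positive)."""
    pred = model.predict(dataset.X)
    cm = confusion(pred, dataset.y, positive=positive)
    return metrics(cm), cm


def window_size_sweep(
    scene,
    sizes: Sequence[int] = (7, 15, 21),
    spec: ClassifierSpec = ClassifierSpec("RF"),
    split: SplitSpec = SplitSpec(),
    seed: int = 1337,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Held-out accuracy as a function of the GLCM window size.

    Re-runs texture extraction, training and evaluation per size on the same
    scene with the same split seed.
    """
    from . import pipeline  # late import to avoid a module cycle

    for s in sizes:
        if s < 3 or s % 2 == 0:
            raise ValidationError(f"window sizes must be odd and >= 3; got {s}")
        if s > min(scene.hires_ms.shape[1:]):
            raise ValidationError(f"window {s} exceeds scene extent")
    rows = []
    for s in sizes:
        report, _ = pipeline.run_interval(
            scene, spec=spec, split=split, window=s, seed=seed,
            **pipeline_kwargs,
        )
        rows.append({"window": s, "accuracy": report.accuracy})
    return pd.DataFrame(rows).set_index("window")


# ---------------------------------------------------------------------------
# Classification maps
# ---------------------------------------------------------------------------

_WHEAT = 1


def classification_map(
    model: TrainedModel,
    feature_maps: Mapping[str, np.ndarray],
    labels: LabelRaster,
    positive: int = _WHEAT,
    min_fp_area: int = 9,
) -> tuple[np.ndarray, pd.DataFrame, ConfusionMatrix]:
    """Per-pixel prediction raster plus field-level markers.

    Each connected labeled field receives a marker at its centroid from the
    majority vote of the pixel predictions inside it: green circle when the
    majority matches the field's class (TP for positive-class fields), red X
    when a positive-class field is missed, purple square when a field is
    assigned the wrong class (or a background blob of at least
    ``min_fp_area`` pixels is predicted as the positive class).  Returns the
    prediction grid, the marker table and the field-level confusion matrix
    (positive class vs rest over labeled fields).
    """
    missing = [f for f in FEATURE_ORDER if f not in feature_maps]
    if missing:
        raise ValidationError(f"missing feature maps {missing}")
    shape = labels.shape
    X = np.column_stack(
        [np.asarray(feature_maps[f], dtype=float).ravel() for f in FEATURE_ORDER]
    )
    finite = np.isfinite(X).all(axis=1)
    pred_flat = np.zeros(X.shape[0], dtype=int)
    if finite.any():
        pred_flat[finite] = model.predict(X[finite])
    pred = pred_flat.reshape(shape)

    field_ids, n_fields = ndimage.label(labels.values > 0)
    markers = []
    tp = fp = fn = tn = 0
    for fid in range(1, n_fields + 1):
        mask = field_ids == fid
        true_class = int(np.bincount(labels.values[mask]).argmax())
        votes = np.bincount(pred[mask], minlength=3)
        pred_class = int(votes.argmax())
        r, c = (float(np.mean(v)) for v in np.nonzero(mask))
        if pred_class == true_class:
            kind = "correct"
        elif pred_class == 0:
            kind = "missed"
        else:
            kind = "misclassified"
        markers.append(
            {"row": r, "col": c, "true_class": true_class,
             "pred_class": pred_class, "kind": kind}
        )
        if true_class == positive:
            if pred_class == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pred_class == positive:
                fp += 1
            else:
                tn += 1

    # false detections: background blobs predicted as the positive class
    bg_pred = (pred == positive) & (labels.values == 0)
    blob_ids, n_blobs = ndimage.label(bg_pred)
    for bid in range(1, n_blobs + 1):
        mask = blob_ids == bid
        if mask.sum() < min_fp_area:
            continue
        r, c = (float(np.mean(v)) for v in np.nonzero(mask))
        markers.append(
            {"row": r, "col": c, "true_class": 0, "pred_class": positive,
             "kind": "false_detection"}
        )
    cm = ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=tn)
    return pred, pd.DataFrame(markers), cm


def render_classification_map(
    pred: np.ndarray, labels: LabelRaster, markers: pd.DataFrame, path
) -> None:
    """Save a marker-overlay figure (green o / red X / purple s)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(pred, cmap="YlGn", interpolation="nearest")
    styles = {
        "correct": dict(marker="o", color="green"),
        "missed": dict(marker="x", color="red"),
        "misclassified": dict(marker="s", color="purple"),
        "false_detection": dict(marker="s", color="purple"),
    }
    for kind, style in styles.items():
        sub = markers[markers["kind"] == kind]
        if len(sub):
            ax.scatter(sub["col"], sub["row"], s=80, facecolors="none",
                       edgecolors=style["color"], marker=style["marker"],
                       linewidths=2, label=kind)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("field-level classification outcome")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
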
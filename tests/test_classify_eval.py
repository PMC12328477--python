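import numpy as np
import pandas as pd
import pytest

from cropfusion.classify_eval import (
    ClassifierSpec,
    ConfusionMatrix,
    SplitSpec,
    classification_map,
    confusion,
    metrics,
    split_dataset,
    split_sizes,
    train_classifier,
)
from cropfusion.errors import CapabilityError, ValidationError
from cropfusion.feature_fusion import FEATURE_ORDER, FeatureDataset
from cropfusion.raster_model import LabelRaster


def blobs_dataset(rng, n_per_class=150, separation=3.0, interval="T4"):
    """Two Gaussian blobs in 6-D, separable along the spectral columns."""
    X = rng.normal(0, 0.4, (2 * n_per_class, 6))
    X[n_per_class:, 4:] += separation
    frame = pd.DataFrame(X, columns=list(FEATURE_ORDER))
    frame["label"] = [1] * n_per_class + [2] * n_per_class
    return FeatureDataset(frame=frame, interval=interval)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n,expected",
    [(40000, (32000, 4000, 4000)), (60000, (48000, 6000, 6000)),
     (45000, (36000, 4500, 4500)), (10, (8, 1, 1))],
)
def test_split_sizes_80_10_10(n, expected):
    assert split_sizes(n, (0.8, 0.1, 0.1)) == expected


def test_split_dataset_exact_sizes_disjoint_exhaustive(rng):
    ds = blobs_dataset(rng, n_per_class=100)
    train, val, test = split_dataset(ds, SplitSpec(seed=7))
    assert (len(train), len(val), len(test)) == (160, 20, 20)
    rows = pd.concat([train.frame, val.frame, test.frame])
    assert len(rows.drop_duplicates()) == 200


def test_split_deterministic_per_seed(rng):
    ds = blobs_dataset(rng, n_per_class=20)
    a = split_dataset(ds, SplitSpec(seed=5))
    b = split_dataset(ds, SplitSpec(seed=5))
    c = split_dataset(ds, SplitSpec(seed=6))
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x.frame, y.frame)
    assert not a[2].frame.equals(c[2].frame)


def test_split_stratification_preserves_class_balance(rng):
    ds = blobs_dataset(rng, n_per_class=100)
    train, val, test = split_dataset(ds, SplitSpec(seed=3))
    for part in (train, val, test):
        counts = np.bincount(part.y, minlength=3)
        assert abs(counts[1] - counts[2]) <= 1


def test_split_tiny_class_rejected_under_stratification(rng):
    frame = blobs_dataset(rng, n_per_class=30).frame
    frame.loc[frame.index[:59], "label"] = 1  # leaves one maize row
    ds = FeatureDataset(frame=frame)
    with pytest.raises(ValidationError):
        split_dataset(ds, SplitSpec())


def test_split_spec_validation():
    with pytest.raises(ValidationError):
        SplitSpec(fractions=(0.8, 0.1, 0.2))
    with pytest.raises(ValidationError):
        SplitSpec(fractions=(1.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_unknown_classifier_rejected():
    with pytest.raises(ValidationError):
        ClassifierSpec("AdaBoost")
    with pytest.raises(ValidationError):
        ClassifierSpec("RF", hyperparams={"bogus": 1}).resolved()


def test_single_class_training_rejected(rng):
    ds = blobs_dataset(rng, n_per_class=20)
    frame = ds.frame[ds.frame["label"] == 1]
    with pytest.raises(ValidationError):
        train_classifier(ClassifierSpec("RF"),
                         FeatureDataset(frame=frame.reset_index(drop=True)))


def test_missing_backend_raises_capability_error(rng, monkeypatch):
    import builtins

    real_import = builtins.__import__

    def no_catboost(name, *args, **kwargs):
        if name == "catboost":
            raise ImportError("no module named catboost")
        return real_import(name, *args, **kwargs)

    monkeypatch.setattr(builtins, "__import__", no_catboost)
    with pytest.raises(CapabilityError, match="CatBoost"):
        train_classifier(ClassifierSpec("CatBoost"), blobs_dataset(rng, 20))


@pytest.mark.parametrize("name", ["RF", "DT", "SVM", "DNN"])
def test_backends_learn_separable_blobs(rng, name):
    ds = blobs_dataset(rng)
    train, _val, test = split_dataset(ds, SplitSpec(seed=1))
    model = train_classifier(ClassifierSpec(name), train, seed=1)
    acc = (model.predict(test.X) == test.y).mean()
    assert acc > 0.95


def test_training_is_seeded(rng):
    ds = blobs_dataset(rng)
    train, _, test = split_dataset(ds, SplitSpec(seed=1))
    m1 = train_classifier(ClassifierSpec("RF"), train, seed=9)
    m2 = train_classifier(ClassifierSpec("RF"), train, seed=9)
    np.testing.assert_array_equal(m1.predict(test.X), m2.predict(test.X))


def test_permuted_labels_score_at_chance(rng):
    """With the label-feature link destroyed, held-out accuracy is binomial
    around 0.5 (3-sigma band)."""
    ds = blobs_dataset(rng, n_per_class=300)
    frame = ds.frame.copy()
    frame["label"] = rng.permutation(frame["label"].to_numpy())
    ds = FeatureDataset(frame=frame, interval=ds.interval)
    train, _, test = split_dataset(ds, SplitSpec(seed=2))
    model = train_classifier(ClassifierSpec("RF"), train, seed=2)
    acc = (model.predict(test.X) == test.y).mean()
    n = len(test)
    assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / n)


# ---------------------------------------------------------------------------
# confusion and metrics
# ---------------------------------------------------------------------------


def test_confusion_perfect_prediction():
    truth = [1] * 10 + [2] * 10
    cm = confusion(truth, truth, positive=1)
    assert (cm.TP, cm.TN, cm.FP, cm.FN) == (10, 10, 0, 0)


def test_confusion_all_positive_prediction():
    truth = [1] * 10 + [2] * 10
    cm = confusion([1] * 20, truth, positive=1)
    assert (cm.TP, cm.FP, cm.FN, cm.TN) == (10, 10, 0, 0)


def test_confusion_matches_naive_tally(rng):
    pred = rng.integers(1, 3, 30)
    truth = rng.integers(1, 3, 30)
    cm = confusion(pred, truth, positive=1)
    tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t != 1)
    fn = sum(1 for p, t in zip(pred, truth) if p != 1 and t == 1)
    tn = sum(1 for p, t in zip(pred, truth) if p != 1 and t != 1)
    assert (cm.TP, cm.FP, cm.FN, cm.TN) == (tp, fp, fn, tn)
    assert cm.total == 30


def test_metrics_identities(rng):
    cm = ConfusionMatrix(TP=40, FP=7, FN=5, TN=48)
    rep = metrics(cm)
    assert rep.accuracy == (40 + 48) / 100
    assert rep.precision == 40 / 47
    assert rep.recall == 40 / 45
    harmonic = 2 / (1 / rep.precision + 1 / rep.recall)
    assert abs(rep.f1 - harmonic) < 1e-12


def test_metrics_degenerate_counts_warn_and_nan():
    with pytest.warns(UserWarning):
        rep = metrics(ConfusionMatrix(TP=0, FP=0, FN=0, TN=0))
    assert all(np.isnan(v) for v in rep.as_dict().values())
    with pytest.warns(UserWarning):
        rep = metrics(ConfusionMatrix(TP=0, FP=0, FN=5, TN=5))
    assert np.isnan(rep.precision)
    assert rep.recall == 0.0


def test_metrics_percent_rounding():
    rep = metrics(ConfusionMatrix(TP=9900, FP=100, FN=1350, TN=0))
    pct = rep.as_percent()
    assert pct["precision"] == 99
    assert pct["recall"] == 88
    assert pct["f1"] == 93


# ---------------------------------------------------------------------------
# classification map
# ---------------------------------------------------------------------------


class _StubModel:
    def __init__(self, constant):
        self.constant = constant

    def predict(self, X):
        return np.full(len(X), self.constant, dtype=int)


def _field_scene(rng):
    labels = np.zeros((30, 30), dtype=int)
    labels[2:8, 2:8] = 1
    labels[2:8, 12:18] = 1
    labels[12:18, 2:8] = 2
    labels[22:28, 22:28] = 2
    maps = {f: rng.random((30, 30)) for f in FEATURE_ORDER}
    return maps, LabelRaster(values=labels)


def test_map_perfect_model_all_green(rng):
    maps, labels = _field_scene(rng)
    # a model that reads the answer from a feature plane
    maps["NDVI"] = labels.values.astype(float)

    class Oracle:
        def predict(self, X):
            return X[:, FEATURE_ORDER.index("NDVI")].astype(int)

    pred, markers, cm = classification_map(Oracle(), maps, labels)
    assert set(markers["kind"]) == {"correct"}
    assert (cm.TP, cm.FN, cm.FP, cm.TN) == (2, 0, 0, 2)


def test_map_all_background_model_misses_fields(rng):
    maps, labels = _field_scene(rng)
    pred, markers, cm = classification_map(_StubModel(0), maps, labels)
    assert (pred == 0).all()
    assert set(markers["kind"]) == {"missed"}
    assert len(markers) == 4
    assert (cm.TP, cm.FN, cm.FP, cm.TN) == (0, 2, 0, 2)


def test_map_marker_counts_match_field_confusion(rng):
    maps, labels = _field_scene(rng)
    pred, markers, cm = classification_map(_StubModel(1), maps, labels)
    field_markers = markers[markers["kind"] != "false_detection"]
    green = (field_markers["kind"] == "correct").sum()
    wrong = (field_markers["kind"] == "misclassified").sum()
    assert cm.TP == ((field_markers["true_class"] == 1)
                     & (field_markers["pred_class"] == 1)).sum() == 2
    assert cm.FP == 2  # both maize fields called wheat
    assert green == 2 and wrong == 2
    # the wheat-predicted background forms false-detection markers
    assert (markers["kind"] == "false_detection").sum() >= 1
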
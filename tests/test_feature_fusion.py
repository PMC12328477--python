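import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cropfusion.errors import DegenerateInputError, ValidationError
from cropfusion.feature_fusion import (
    FEATURE_ORDER,
    SPECTRAL_FEATURES,
    TEXTURAL_FEATURES,
    FeatureDataset,
    FeatureProfile,
    FWMWeights,
    apply_weights,
    assemble_time_series,
    fwm_weights,
    improvement_report,
    round_half_up,
    standardized_distance,
)
from cropfusion.raster_model import LabelRaster


def _profiles(means, sds):
    return [
        FeatureProfile(name=n, mean=m, sd=s)
        for n, m, s in zip(FEATURE_ORDER, means, sds)
    ]


profile_lists = st.lists(
    st.tuples(st.floats(-1, 1), st.floats(0.01, 0.5)),
    min_size=6, max_size=6,
).map(lambda ps: _profiles([p[0] for p in ps], [p[1] for p in ps]))


# ---------------------------------------------------------------------------
# standardized distance
# ---------------------------------------------------------------------------


def test_distance_identical_profiles_is_zero():
    a = FeatureProfile("NDVI", 0.5, 0.1)
    b = FeatureProfile("EVI", 0.5, 0.1)
    assert standardized_distance(a, b) == 0.0


def test_distance_fused_ndvi_example():
    """|0.78 - 0.61| / (0.04 + 0.03) = 2.4286 (fused NDVI vs fused EVI)."""
    a = FeatureProfile("NDVI", 0.78, 0.04)
    b = FeatureProfile("EVI", 0.61, 0.03)
    assert np.isclose(standardized_distance(a, b), 0.17 / 0.07)


def test_distance_zero_deviations_degenerate():
    a = FeatureProfile("NDVI", 0.5, 0.0)
    b = FeatureProfile("EVI", 0.4, 0.0)
    with pytest.raises(DegenerateInputError):
        standardized_distance(a, b)


def test_distance_magnitude_symmetric():
    a = FeatureProfile("NDVI", 0.7, 0.05)
    b = FeatureProfile("contrast", 0.2, 0.02)
    assert standardized_distance(a, b) == standardized_distance(b, a)
    assert standardized_distance(a, b, absolute=False) == -standardized_distance(
        b, a, absolute=False
    )


# ---------------------------------------------------------------------------
# FWM weights
# ---------------------------------------------------------------------------


def naive_fwm(profiles):
    """Brute-force reference: enumerate pairs, mean per feature, per group."""
    by_name = {p.name: p for p in profiles}
    dist = {}
    for na, nb in itertools.combinations(FEATURE_ORDER, 2):
        a, b = by_name[na], by_name[nb]
        dist[(na, nb)] = abs((a.mean - b.mean) / (a.sd + b.sd))
    score = {}
    for name in FEATURE_ORDER:
        vals = [d for pair, d in dist.items() if name in pair]
        score[name] = sum(vals) / len(vals)
    ds = sum(score[n] for n in SPECTRAL_FEATURES) / 2
    dt = sum(score[n] for n in TEXTURAL_FEATURES) / 4
    return ds / (ds + dt), dt / (ds + dt)


def test_fwm_all_identical_profiles_degenerate():
    profiles = _profiles([0.5] * 6, [0.1] * 6)
    with pytest.raises(DegenerateInputError):
        fwm_weights(profiles)


def test_fwm_symmetric_construction_gives_equal_weights():
    """Spectral {A,B} vs textural {A,B,A,B}: symmetry forces w1 = w2 = 0.5."""
    A, B = (0.2, 0.05), (0.8, 0.05)
    means_sds = {"EVI": A, "NDVI": B, "correlation": A, "contrast": B,
                 "energy": A, "entropy": B}
    profiles = [FeatureProfile(n, *means_sds[n]) for n in FEATURE_ORDER]
    w = fwm_weights(profiles)
    assert np.isclose(w.w1, 0.5)
    assert np.isclose(w.w2, 0.5)


@given(profile_lists)
def test_fwm_matches_naive_enumeration_and_sums_to_one(profiles):
    try:
        w = fwm_weights(profiles)
    except DegenerateInputError:
        return
    w1_ref, w2_ref = naive_fwm(profiles)
    assert np.isclose(w.w1, w1_ref)
    assert np.isclose(w.w2, w2_ref)
    assert w.w1 >= 0 and w.w2 >= 0
    assert np.isclose(w.w1 + w.w2, 1.0)


def test_fwm_invariant_under_within_group_permutation(rng):
    means = rng.uniform(0, 1, 6)
    sds = rng.uniform(0.01, 0.2, 6)
    profiles = _profiles(means, sds)
    w = fwm_weights(profiles)
    # swap the stats of two textural features
    swapped = {p.name: p for p in profiles}
    a, b = swapped["contrast"], swapped["energy"]
    swapped["contrast"] = FeatureProfile("contrast", b.mean, b.sd)
    swapped["energy"] = FeatureProfile("energy", a.mean, a.sd)
    w2 = fwm_weights(list(swapped.values()))
    assert np.isclose(w.w1, w2.w1)


def test_fwm_cross_pair_set_is_constant_half(rng):
    profiles = _profiles(rng.uniform(0, 1, 6), rng.uniform(0.01, 0.2, 6))
    w = fwm_weights(profiles, pair_set="cross")
    assert np.isclose(w.w1, 0.5)
    assert len(w.distances) == 8


def test_fwm_requires_all_six_features():
    profiles = _profiles(np.linspace(0.1, 0.6, 6), [0.1] * 6)[:5]
    with pytest.raises(ValidationError):
        fwm_weights(profiles)


# ---------------------------------------------------------------------------
# apply_weights
# ---------------------------------------------------------------------------


def _dataset(rng, n=40, interval="T1"):
    frame = pd.DataFrame(
        {f: rng.random(n) for f in FEATURE_ORDER}
        | {"label": rng.integers(1, 3, n), "row": np.arange(n),
           "col": np.arange(n)}
    )
    return FeatureDataset(frame=frame, interval=interval)


def test_apply_weights_halves_all_columns(rng):
    ds = _dataset(rng)
    out = apply_weights(ds, FWMWeights(0.5, 0.5))
    np.testing.assert_allclose(out.X, ds.X / 2)
    np.testing.assert_array_equal(out.y, ds.y)


def test_apply_weights_boundary_zeroes_textural(rng):
    ds = _dataset(rng)
    out = apply_weights(ds, FWMWeights(1.0, 0.0))
    for name in TEXTURAL_FEATURES:
        assert (out.frame[name] == 0).all()
    for name in SPECTRAL_FEATURES:
        np.testing.assert_allclose(out.frame[name], ds.frame[name])


def test_positive_scaling_preserves_separability(rng):
    """Column scaling by positive weights leaves a separable problem separable."""
    from cropfusion.classify_eval import ClassifierSpec, train_classifier

    n = 150
    X = rng.normal(0, 0.3, (2 * n, 6))
    X[n:, 4:] += 4.0  # classes split along the spectral columns
    frame = pd.DataFrame(X, columns=list(FEATURE_ORDER))
    frame["label"] = [1] * n + [2] * n
    ds = FeatureDataset(frame=frame)
    scaled = apply_weights(ds, FWMWeights(0.7, 0.3))
    for data in (ds, scaled):
        model = train_classifier(ClassifierSpec("DT"), data, seed=0)
        assert (model.predict(data.X) == data.y).mean() > 0.95


def test_fwm_weights_validation():
    with pytest.raises(ValidationError):
        FWMWeights(0.7, 0.7)
    with pytest.raises(ValidationError):
        FWMWeights(-0.2, 1.2)


# ---------------------------------------------------------------------------
# improvement report
# ---------------------------------------------------------------------------

ORIGINAL = {
    "NDVI": (0.62, 0.07), "EVI": (0.45, 0.05), "correlation": (0.43, 0.04),
    "contrast": (0.15, 0.02), "energy": (0.11, 0.01), "entropy": (0.41, 0.05),
}
FUSED = {
    "NDVI": (0.78, 0.04), "EVI": (0.61, 0.03), "correlation": (0.63, 0.03),
    "contrast": (0.27, 0.01), "energy": (0.18, 0.02), "entropy": (0.27, 0.02),
}


def test_improvement_report_worked_values():
    table = improvement_report(ORIGINAL, FUSED)
    assert table.loc["NDVI", "improvement_pct"] == 25.8
    assert table.loc["contrast", "improvement_pct"] == 80.0
    assert table.loc["entropy", "improvement_pct"] == -34.1


def test_improvement_report_identity_is_zero():
    table = improvement_report(ORIGINAL, ORIGINAL)
    assert (table["improvement_pct"] == 0).all()


def test_improvement_report_zero_mean_is_nodata():
    table = improvement_report({"NDVI": (0.0, 0.1)}, {"NDVI": (0.5, 0.1)})
    assert np.isnan(table.loc["NDVI", "improvement_pct"])


def test_improvement_report_feature_set_mismatch():
    with pytest.raises(ValidationError):
        improvement_report({"NDVI": (0.5, 0.1)}, {"EVI": (0.5, 0.1)})


def test_round_half_up_behaviour():
    assert round_half_up(25.85, 1) == 25.9
    assert round_half_up(-34.15, 1) == -34.2
    assert round_half_up(0.935, 2) == 0.94


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _maps(rng, shape):
    return {f: rng.random(shape) for f in FEATURE_ORDER}


def test_assemble_counts_labeled_pixels_only(rng):
    labels = np.zeros((20, 20), dtype=int)
    labels[:5, :20] = 1  # 100 wheat
    labels[10:15, :20] = 2  # 100 maize
    lab = LabelRaster(values=labels)
    (ds,) = assemble_time_series({"T2": _maps(rng, (20, 20))}, lab,
                                 cap_per_interval=None)
    assert len(ds) == 200
    assert set(np.unique(ds.y)) == {1, 2}
    assert ds.interval == "T2"


def test_assemble_stratified_cap_preserves_proportions(rng):
    labels = np.zeros((20, 20), dtype=int)
    labels[:6] = 1  # 120 wheat
    labels[14:] = 2  # 120 maize
    lab = LabelRaster(values=labels)
    (ds,) = assemble_time_series({"T1": _maps(rng, (20, 20))}, lab,
                                 cap_per_interval=50)
    assert len(ds) == 50
    counts = np.bincount(ds.y)
    assert abs(counts[1] - counts[2]) <= 1


def test_assemble_no_labeled_pixels_rejected(rng):
    lab = LabelRaster(values=np.zeros((8, 8), dtype=int))
    with pytest.raises(ValidationError):
        assemble_time_series({"T1": _maps(rng, (8, 8))}, lab)


def test_assemble_five_intervals_in_order(rng):
    labels = np.zeros((8, 8), dtype=int)
    labels[:4] = 1
    labels[6:] = 2
    lab = LabelRaster(values=labels)
    maps = {t: _maps(rng, (8, 8)) for t in ("T1", "T2", "T3", "T4", "T5")}
    datasets = assemble_time_series(maps, lab)
    assert [d.interval for d in datasets] == ["T1", "T2", "T3", "T4", "T5"]


def test_assemble_drops_nonfinite_vectors(rng):
    labels = np.zeros((8, 8), dtype=int)
    labels[:4] = 1
    labels[6:] = 2
    maps = _maps(rng, (8, 8))
    maps["NDVI"][0, 0] = np.nan
    (ds,) = assemble_time_series({"T1": maps}, LabelRaster(values=labels),
                                 cap_per_interval=None)
    assert len(ds) == labels.astype(bool).sum() - 1
    assert np.isfinite(ds.X).all()


def test_dataset_csv_round_trip(rng, tmp_path):
    ds = _dataset_for_csv(rng)
    path = tmp_path / "t3.csv"
    ds.to_csv(path)
    back = FeatureDataset.from_csv(path)
    np.testing.assert_allclose(back.X, ds.X)
    np.testing.assert_array_equal(back.y, ds.y)
    assert back.interval == "T3"


def _dataset_for_csv(rng):
    frame = pd.DataFrame(
        {f: rng.random(10) for f in FEATURE_ORDER}
        | {"label": rng.integers(1, 3, 10)}
    )
    return FeatureDataset(frame=frame, interval="T3")
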
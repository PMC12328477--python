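"""Feature Weighting Method (FWM) and feature-table assembly.

Each of the six features (four GLCM texture statistics plus EVI and NDVI)
is summarised by its time-profile mean and standard deviation.  The
standardized distance between two features is

    d = (x_bar_i - x_bar_j) / (s_i + s_j)

and the spectral (m = 2) and textural (n = 4) feature groups receive
weights w1, w2 proportional to the mean absolute standardized distance
attributed to each group, normalized so w1 + w2 = 1.  Weighted feature
vectors are the classifier input.

The printed form of the group-weight equations in the source material is
internally inconsistent (the two weights do not sum to any fixed constant
and the index ranges overlap), and a pair set restricted to
spectral x textural cross pairs makes any symmetric attribution
data-independent.  The implemented, well-defined form therefore scores
every feature by its mean absolute standardized distance to all other
features (all 15 unordered pairs by default; restrictable to the 8 cross
pairs), averages the scores within each group, and normalizes the two
group scores to sum to 1.  This preserves the stated intent — weights in
proportion to standardized distances — while being reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .raster_model import LabelRaster

__all__ = [
    "FEATURE_ORDER",
    "SPECTRAL_FEATURES",
    "TEXTURAL_FEATURES",
    "FeatureProfile",
    "FWMWeights",
    "FeatureDataset",
    "standardized_distance",
    "fwm_weights",
    "apply_weights",
    "improvement_report",
    "assemble_time_series",
    "profiles_from_dataset",
    "round_half_up",
]

#: Fixed feature-vector column order.
FEATURE_ORDER = ("correlation", "contrast", "energy", "entropy", "EVI", "NDVI")
SPECTRAL_FEATURES = ("EVI", "NDVI")
TEXTURAL_FEATURES = ("correlation", "contrast", "energy", "entropy")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to the given number of decimals."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class FeatureProfile:
    """Time-profile summary of one feature: mean and standard deviation."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.name not in FEATURE_ORDER:
            raise ValidationError(
                f"unknown feature {self.name!r}; expected one of {FEATURE_ORDER}"
            )
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")

    @property
    def group(self) -> str:
        return "spectral" if self.name in SPECTRAL_FEATURES else "textural"


@dataclass(frozen=True)
class FWMWeights:
    """Spectral/textural group weights plus the distances behind them."""

    w1: float  # spectral
    w2: float  # textural
    distances: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValidationError("weights must be non-negative")
        if not math.isclose(self.w1 + self.w2, 1.0, abs_tol=1e-9):
            raise ValidationError("weights must sum to 1")


def standardized_distance(
    a: FeatureProfile, b: FeatureProfile, absolute: bool = True
) -> float:
    """Standardized distance between two feature profiles.

    ``(mean_a - mean_b) / (sd_a + sd_b)``; the absolute value is taken by
    default since the sign depends only on argument order.
    """
    denom = a.sd + b.sd
    if denom == 0:
        raise DegenerateInputError(
            f"both deviations are zero for {a.name}/{b.name}"
        )
    d = (a.mean - b.mean) / denom
    return abs(d) if absolute else d


def fwm_weights(
    profiles: Sequence[FeatureProfile], pair_set: str = "all"
) -> FWMWeights:
    """Spectral/textural group weights from six feature profiles.

    Parameters
    ----------
    profiles:
        Exactly the six features of :data:`FEATURE_ORDER` (any order).
    pair_set:
        ``"all"`` (default) uses all 15 unordered pairs; ``"cross"``
        restricts to the 8 spectral x textural pairs (which makes the
        weights constant at 0.5 — retained for comparison only).
    """
    by_name = {p.name: p for p in profiles}
    if set(by_name) != set(FEATURE_ORDER) or len(profiles) != len(FEATURE_ORDER):
        raise ValidationError(
            f"need exactly the six features {FEATURE_ORDER}; got "
            f"{sorted(p.name for p in profiles)}"
        )
    if pair_set not in ("all", "cross"):
        raise ValidationError("pair_set must be 'all' or 'cross'")

    pairs = []
    for na, nb in combinations(FEATURE_ORDER, 2):
        a, b = by_name[na], by_name[nb]
        if pair_set == "cross" and a.group == b.group:
            continue
        pairs.append((na, nb, standardized_distance(a, b)))

    if all(d == 0 for _, _, d in pairs):
        raise DegenerateInputError("all standardized distances are zero")

    scores = {}
    for name in FEATURE_ORDER:
        ds = [d for na, nb, d in pairs if name in (na, nb)]
        scores[name] = float(np.mean(ds)) if ds else 0.0
    d_spectral = float(np.mean([scores[n] for n in SPECTRAL_FEATURES]))
    d_textural = float(np.mean([scores[n] for n in TEXTURAL_FEATURES]))
    total = d_spectral + d_textural
    if total == 0:
        raise DegenerateInputError("group distance scores are both zero")
    return FWMWeights(
        w1=d_spectral / total, w2=d_textural / total, distances=tuple(pairs)
    )


# ---------------------------------------------------------------------------
# Feature datasets
# ---------------------------------------------------------------------------


@dataclass
class FeatureDataset:
    """A table of 6-dimensional feature vectors with labels and provenance.

    ``frame`` columns: the six features of :data:`FEATURE_ORDER`, ``label``
    (class code), ``row`` and ``col`` (source pixel coordinates).
    """

    frame: pd.DataFrame
    interval: str = "T1"

    def __post_init__(self) -> None:
        missing = [c for c in (*FEATURE_ORDER, "label") if c not in self.frame]
        if missing:
            raise ValidationError(f"dataset frame lacks columns {missing}")
        feat = self.frame[list(FEATURE_ORDER)].to_numpy(dtype=float)
        if not np.isfinite(feat).all():
            raise ValidationError("feature vectors contain non-finite entries")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_ORDER)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["interval"] = self.interval
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        frame = pd.read_csv(path)
        interval = str(frame["interval"].iloc[0]) if "interval" in frame else "T1"
        return cls(frame=frame.drop(columns=["interval"], errors="ignore"),
                   interval=interval)


def apply_weights(dataset: FeatureDataset, w: FWMWeights) -> FeatureDataset:
    """Scale spectral columns by w1 and textural columns by w2."""
    frame = dataset.frame.copy()
    for name in SPECTRAL_FEATURES:
        frame[name] = frame[name] * w.w1
    for name in TEXTURAL_FEATURES:
        frame[name] = frame[name] * w.w2
    return FeatureDataset(frame=frame, interval=dataset.interval)


def profiles_from_dataset(dataset: FeatureDataset) -> list[FeatureProfile]:
    """Per-feature mean/sd profiles of a feature table."""
    return [
        FeatureProfile(
            name=name,
            mean=float(dataset.frame[name].mean()),
            sd=float(dataset.frame[name].std(ddof=0)),
        )
        for name in FEATURE_ORDER
    ]


def improvement_report(
    original: Mapping[str, tuple[float, float]],
    fused: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Percent change of per-feature means between two feature sets.

    ``improvement_pct = (fused_mean - original_mean) / original_mean * 100``
    rounded half-up to one decimal; NaN where the original mean is zero.
    """
    if set(original) != set(fused):
        raise ValidationError("original and fused must cover the same features")
    rows = []
    for name in original:
        om, osd = original[name]
        fm, fsd = fused[name]
        pct = (
            float("nan") if om == 0 else round_half_up((fm - om) / om * 100.0, 1)
        )
        rows.append(
            {
                "feature": name,
                "original_mean": om,
                "original_sd": osd,
                "fused_mean": fm,
                "fused_sd": fsd,
                "improvement_pct": pct,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def _stratified_cap(
    labels: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a stratified subsample of at most ``cap`` rows.

    Class proportions are preserved to within one sample (largest-remainder
    allocation).
    """
    n = labels.size
    if cap >= n:
        return np.arange(n)
    classes, counts = np.unique(labels, return_counts=True)
    exact = counts * (cap / n)
    alloc = np.floor(exact).astype(int)
    remainder = cap - alloc.sum()
    order = np.argsort(exact - alloc)[::-1]
    for k in order[:remainder]:
        alloc[k] += 1
    keep = []
    for cls, take in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=take, replace=False))
    return np.sort(np.concatenate(keep))


def assemble_time_series(
    feature_maps: Mapping[str, Mapping[str, np.ndarray]],
    labels: LabelRaster | Mapping[str, LabelRaster],
    intervals: Sequence[str] | None = None,
    cap_per_interval: int | None = 2000,
    seed: int = 1337,
) -> list[FeatureDataset]:
    """Build one FeatureDataset per time interval from co-registered maps.

    Parameters
    ----------
    feature_maps:
        ``{interval: {feature name: 2-D map}}`` with all six features of
        :data:`FEATURE_ORDER` per interval.
    labels:
        A single LabelRaster shared by all intervals, or one per interval.
    cap_per_interval:
        Stratified sample cap (class proportions preserved to within one
        vector); ``None`` keeps every labeled pixel.
    """
    intervals = list(intervals if intervals is not None else feature_maps.keys())
    datasets = []
    for k, interval in enumerate(intervals):
        maps = feature_maps[interval]
        missing = [f for f in FEATURE_ORDER if f not in maps]
        if missing:
            raise ValidationError(f"{interval}: missing feature maps {missing}")
        lab = labels[interval] if isinstance(labels, Mapping) else labels
        shape = lab.shape
        for f in FEATURE_ORDER:
            if maps[f].shape != shape:
                raise ValidationError(
                    f"{interval}/{f}: map shape {maps[f].shape} != labels {shape}"
                )
        rows, cols = np.nonzero(lab.values)
        if rows.size == 0:
            raise ValidationError(f"{interval}: no labeled pixels")
        data = {f: maps[f][rows, cols] for f in FEATURE_ORDER}
        finite = np.ones(rows.size, dtype=bool)
        for f in FEATURE_ORDER:
            finite &= np.isfinite(data[f])
        frame = pd.DataFrame(
            {
                **{f: data[f][finite] for f in FEATURE_ORDER},
                "label": lab.values[rows, cols][finite],
                "row": rows[finite],
                "col": cols[finite],
            }
        )
        if cap_per_interval is not None and len(frame) > cap_per_interval:
            rng = np.random.default_rng([seed, k])
            idx = _stratified_cap(
                frame["label"].to_numpy(), cap_per_interval, rng
            )
            frame = frame.iloc[idx].reset_index(drop=True)
        datasets.append(FeatureDataset(frame=frame, interval=interval))
    return datasets
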
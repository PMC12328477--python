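"""Synthetic paired-resolution crop scenes with ground-truth labels.

The generator emulates the study conditions of a two-crop (wheat / maize)
landscape observed by a high-resolution multispectral sensor (blue, green,
red, NIR at the fine grid), a coarser six-band sensor (adding two SWIR
bands at ``resolution_ratio`` x coarser pixels) and a fine panchromatic
band.  Crop phenology is encoded as a per-class NDVI trajectory over five
time intervals T1..T5: wheat greens up through winter and peaks at T4
(March), maize stays lower, so the spectral separation of the classes
grows from T1 to T4 and classification is expected to get easier with
later intervals.

Construction, per pixel:

1. an NDVI target ``t`` = class interval mean + per-field offset +
   spatially autocorrelated within-field variation (class-specific
   correlation length, so texture is class-informative);
2. bands from a linear band model with brightness ``a``:
   ``red = a (1 - t)``, ``nir = a (1 + t)`` (hence NDVI of the noise-free
   pixel equals ``t`` exactly), blue/green tied to red by fixed offsets,
   SWIR decreasing in ``t``;
3. a class-textured brightness perturbation added to all bands;
4. the coarse stack is the block mean of the fine-grid radiance plus
   independent sensor noise; the pan band is the mean of the visible +
   NIR bands plus noise.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ValidationError
from .raster_model import LabelRaster, MultibandRaster, make_bands

__all__ = [
    "INTERVALS",
    "CLASS_CODES",
    "SceneConfig",
    "ScenePair",
    "generate_scene",
    "generate_time_series",
    "block_mean",
]

INTERVALS = ("T1", "T2", "T3", "T4", "T5")
CLASS_CODES = {"wheat": 1, "maize": 2}

#: Default per-class NDVI trajectory (mean, sd) per interval.  Wheat peaks
#: at T4; the wheat-maize separation is non-decreasing from T1 to T4.
DEFAULT_TRAJECTORY: dict[str, dict[str, tuple[float, float]]] = {
    "wheat": {
        "T1": (0.30, 0.05), "T2": (0.45, 0.05), "T3": (0.60, 0.05),
        "T4": (0.75, 0.05), "T5": (0.62, 0.05),
    },
    "maize": {
        "T1": (0.28, 0.05), "T2": (0.35, 0.05), "T3": (0.40, 0.05),
        "T4": (0.45, 0.05), "T5": (0.47, 0.05),
    },
}

#: Default per-class texture: (autocorrelation length in pixels, brightness
#: noise amplitude in reflectance units).  Wheat fields carry fine-grained
#: texture, maize fields smoother, larger-scale structure.
DEFAULT_TEXTURE: dict[str, tuple[float, float]] = {
    "wheat": (1.5, 0.012),
    "maize": (5.0, 0.012),
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    ``extent`` is (rows, cols) at the high resolution and must be divisible
    by ``resolution_ratio``.  ``class_mix`` is the target wheat share of
    labeled area.  ``brightness`` is the band-model constant ``a``.
    """

    extent: tuple[int, int] = (96, 96)
    n_fields: int = 24
    class_mix: float = 0.5
    ndvi_trajectory: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_TRAJECTORY
    )
    texture_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_TEXTURE
    )
    background_ndvi: tuple[float, float] = (0.12, 0.02)
    background_texture: tuple[float, float] = (3.0, 0.008)
    brightness: float = 0.25
    resolution_ratio: int = 3
    hires_pixel_size: float = 10.0
    sensor_noise: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_ratio < 2:
            raise ConfigurationError("resolution_ratio must be >= 2")
        if not (0 < self.class_mix < 1):
            raise ConfigurationError("class_mix must be in (0, 1)")
        if self.n_fields < 1:
            raise ConfigurationError("n_fields must be >= 1")
        for cls, traj in self.ndvi_trajectory.items():
            for t, (m, s) in traj.items():
                if not (-1 <= m <= 1) or s < 0:
                    raise ConfigurationError(
                        f"NDVI trajectory {cls}/{t} out of range: ({m}, {s})"
                    )
        wheat = self.ndvi_trajectory.get("wheat", {})
        maize = self.ndvi_trajectory.get("maize", {})
        common = [t for t in INTERVALS if t in wheat and t in maize]
        if common:
            peak = max(common, key=lambda t: wheat[t][0])
            for t in common[: common.index(peak) + 1]:
                if wheat[t][0] < maize[t][0]:
                    raise ConfigurationError(
                        f"wheat NDVI mean must be >= maize up to the wheat "
                        f"peak; violated at {t}"
                    )


@dataclass
class ScenePair:
    """One co-registered synthetic acquisition at one time interval."""

    hires_ms: MultibandRaster
    lores_ms: MultibandRaster
    pan: np.ndarray
    labels: LabelRaster
    interval: str

    def __post_init__(self) -> None:
        hr = self.hires_ms.shape[1:]
        lr = self.lores_ms.shape[1:]
        ratio = hr[0] // lr[0]
        if (lr[0] * ratio, lr[1] * ratio) != hr:
            raise ValidationError(
                f"lores extent {lr} x ratio does not match hires extent {hr}"
            )
        if self.labels.shape != hr:
            raise ValidationError("labels extent must equal hires extent")


def block_mean(grid: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping ``factor x factor`` blocks of a 2-D grid."""
    r, c = grid.shape
    if r % factor or c % factor:
        raise ValidationError(f"extent {grid.shape} not divisible by {factor}")
    return grid.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _field_rectangles(
    config: SceneConfig, rng: np.random.Generator
) -> list[tuple[int, int, int, int]]:
    """Axis-aligned field rectangles (r0, r1, c0, c1) on a jittered grid."""
    rows, cols = config.extent
    g = int(np.ceil(np.sqrt(config.n_fields)))
    cell_r = rows / g
    cell_c = cols / g
    cells = [(i, j) for i in range(g) for j in range(g)]
    rng.shuffle(cells)
    rects = []
    for i, j in cells[: config.n_fields]:
        fr = rng.uniform(0.55, 0.85)
        fc = rng.uniform(0.55, 0.85)
        h = max(3, int(round(fr * cell_r)))
        w = max(3, int(round(fc * cell_c)))
        r0 = int(i * cell_r + rng.uniform(0, cell_r - h)) if cell_r > h else int(i * cell_r)
        c0 = int(j * cell_c + rng.uniform(0, cell_c - w)) if cell_c > w else int(j * cell_c)
        rects.append((r0, min(r0 + h, rows), c0, min(c0 + w, cols)))
    return rects


def _assign_classes(
    rects: list[tuple[int, int, int, int]], class_mix: float
) -> list[str]:
    """Greedy area-balanced class assignment hitting ``class_mix`` closely."""
    areas = [(r1 - r0) * (c1 - c0) for r0, r1, c0, c1 in rects]
    order = np.argsort(areas)[::-1]
    total = sum(areas)
    target_wheat = class_mix * total
    wheat_area = 0.0
    maize_area = 0.0
    classes = [""] * len(rects)
    for k in order:
        # assign to the class furthest below its target share
        if wheat_area / target_wheat <= maize_area / (total - target_wheat):
            classes[k] = "wheat"
            wheat_area += areas[k]
        else:
            classes[k] = "maize"
            maize_area += areas[k]
    return classes


def _smooth_noise(
    shape: tuple[int, int], length: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian noise."""
    white = rng.standard_normal(shape)
    if length <= 0:
        return white
    smooth = gaussian_filter(white, sigma=length, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _interval_index(interval: str) -> int:
    if interval not in INTERVALS:
        raise ConfigurationError(
            f"unknown interval {interval!r}; expected one of {INTERVALS}"
        )
    return INTERVALS.index(interval)


def generate_scene(config: SceneConfig, interval: str) -> ScenePair:
    """Generate one ScenePair for one time interval.

    Field geometry and class assignment depend only on ``config.seed`` (so
    fields do not move between intervals); the noise realisations depend on
    both the seed and the interval.
    """
    rows, cols = config.extent
    ratio = config.resolution_ratio
    if rows % ratio or cols % ratio:
        raise ConfigurationError(
            f"extent {config.extent} not divisible by resolution_ratio {ratio}"
        )
    t_idx = _interval_index(interval)
    for cls in ("wheat", "maize"):
        if interval not in config.ndvi_trajectory.get(cls, {}):
            raise ConfigurationError(
                f"trajectory for class {cls!r} lacks interval {interval!r}"
            )

    geom_rng = np.random.default_rng(config.seed)
    rects = _field_rectangles(config, geom_rng)
    classes = _assign_classes(rects, config.class_mix)
    noise_rng = np.random.default_rng([config.seed, 7919 + t_idx])

    labels = np.zeros((rows, cols), dtype=np.int16)
    ndvi_t = np.full((rows, cols), config.background_ndvi[0], dtype=float)

    bg_len, bg_amp = config.background_texture
    if config.background_ndvi[1] > 0:
        ndvi_t += config.background_ndvi[1] * _smooth_noise(
            (rows, cols), bg_len, noise_rng
        )

    # class texture fields (shared across that class's fields)
    class_noise = {
        cls: _smooth_noise((rows, cols), config.texture_params[cls][0], noise_rng)
        for cls in ("wheat", "maize")
    }
    brightness_noise = np.zeros((rows, cols))
    if bg_amp > 0:
        brightness_noise += bg_amp * _smooth_noise((rows, cols), bg_len, noise_rng)
    class_bright = {
        cls: _smooth_noise((rows, cols), config.texture_params[cls][0], noise_rng)
        for cls in ("wheat", "maize")
    }

    for (r0, r1, c0, c1), cls in zip(rects, classes):
        mean, sd = config.ndvi_trajectory[cls][interval]
        # split sd: half from a per-field offset, the rest within-field
        field_offset = noise_rng.normal(0.0, 0.5 * sd)
        block = (
            mean
            + field_offset
            + (np.sqrt(0.75) * sd) * class_noise[cls][r0:r1, c0:c1]
        )
        ndvi_t[r0:r1, c0:c1] = block
        labels[r0:r1, c0:c1] = CLASS_CODES[cls]
        amp = config.texture_params[cls][1]
        brightness_noise[r0:r1, c0:c1] = amp * class_bright[cls][r0:r1, c0:c1]

    ndvi_t = np.clip(ndvi_t, -1.0, 1.0)

    # band model (fine grid, 6 bands): NDVI of the noise-free pixel == target
    a = config.brightness
    red = a * (1.0 - ndvi_t)
    nir = a * (1.0 + ndvi_t)
    blue = np.clip(red - 0.01, 0.0, None)
    green = red + 0.01
    swir1 = np.clip(0.30 - 0.15 * ndvi_t, 0.0, None)
    swir2 = np.clip(0.25 - 0.12 * ndvi_t, 0.0, None)
    truth = np.stack([blue, green, red, nir, swir1, swir2]) + brightness_noise

    sigma = config.sensor_noise
    hires_vals = truth[:4].copy()
    if sigma > 0:
        hires_vals = hires_vals + noise_rng.normal(0, sigma, hires_vals.shape)
    lores_vals = np.stack([block_mean(b, ratio) for b in truth])
    if sigma > 0:
        lores_vals = lores_vals + noise_rng.normal(0, sigma, lores_vals.shape)
    pan = truth[:4].mean(axis=0)
    if sigma > 0:
        pan = pan + noise_rng.normal(0, sigma, pan.shape)

    px = config.hires_pixel_size
    hires = MultibandRaster(
        values=hires_vals,
        bands=make_bands(("blue", "green", "red", "nir"), px),
        pixel_size=px,
    )
    lores = MultibandRaster(
        values=lores_vals,
        bands=make_bands(
            ("blue", "green", "red", "nir", "swir1", "swir2"), px * ratio
        ),
        pixel_size=px * ratio,
    )
    return ScenePair(
        hires_ms=hires,
        lores_ms=lores,
        pan=pan,
        labels=LabelRaster(values=labels, pixel_size=px),
        interval=interval,
    )


def generate_time_series(config: SceneConfig) -> list[ScenePair]:
    """Generate the five-interval series T1..T5 with shared field geometry."""
    for cls in ("wheat", "maize"):
        traj = config.ndvi_trajectory.get(cls, {})
        missing = [t for t in INTERVALS if t not in traj]
        if missing:
            raise ConfigurationError(
                f"trajectory for class {cls!r} lacks intervals {missing}"
            )
    return [generate_scene(config, t) for t in INTERVALS]
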
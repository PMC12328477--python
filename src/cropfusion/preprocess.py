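"""Radiometric scaling, dark-object subtraction, cubic-convolution resampling
and false-colour compositing.

These are the standard conditioning steps applied to both multispectral
stacks before fusion: a linear gain/offset per band to put sensors on a
common radiometric scale, a first-order atmospheric correction that
subtracts each band's scene minimum (dark-object subtraction), and
resampling to a common grid with the piecewise-cubic Keys kernel
(``a = -0.5``), the classic "cubic convolution" that averages the 4x4
source neighbourhood around every output sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import RoleLookupError, ValidationError
from .raster_model import BandMeta, MultibandRaster, band_by_role

__all__ = [
    "CalibrationCoeffs",
    "radiometric_calibrate",
    "dark_object_subtraction",
    "resample_cubic",
    "false_color_composite",
]


@dataclass(frozen=True)
class CalibrationCoeffs:
    """Per-band linear calibration: ``out = gain * DN + offset``."""

    gain: tuple[float, ...]
    offset: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.gain) != len(self.offset):
            raise ValidationError("gain and offset lists must have equal length")
        if any(g == 0 for g in self.gain):
            raise ValidationError("gain must be nonzero for every band")

    @classmethod
    def identity(cls, n_bands: int) -> "CalibrationCoeffs":
        return cls(gain=(1.0,) * n_bands, offset=(0.0,) * n_bands)


def radiometric_calibrate(
    raster: MultibandRaster, coeffs: CalibrationCoeffs
) -> MultibandRaster:
    """Apply ``gain * DN + offset`` per band; nodata pixels are untouched."""
    if len(coeffs.gain) != raster.n_bands:
        raise ValidationError(
            f"{len(coeffs.gain)} coefficient pairs for {raster.n_bands} bands"
        )
    out = raster.values.astype(float).copy()
    for b in range(raster.n_bands):
        valid = raster.valid_mask(b)
        out[b][valid] = coeffs.gain[b] * out[b][valid] + coeffs.offset[b]
    return raster.with_values(out)


def dark_object_subtraction(raster: MultibandRaster) -> MultibandRaster:
    """Subtract each band's minimum valid value so the new minimum is 0.

    Assumes each scene contains a truly dark object; the per-band scene
    minimum is taken as the additive atmospheric path radiance.  Idempotent.
    """
    out = raster.values.astype(float).copy()
    for b in range(raster.n_bands):
        valid = raster.valid_mask(b)
        if not valid.any():
            raise ValidationError(f"band {b} has no valid pixels")
        out[b][valid] -= out[b][valid].min()
    return raster.with_values(out)


# ---------------------------------------------------------------------------
# Cubic convolution (Keys kernel)
# ---------------------------------------------------------------------------


def keys_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys piecewise-cubic interpolation kernel.

    With ``a = -0.5`` the scheme is third-order accurate and reproduces
    polynomials up to degree 2 exactly.  Support is ``|x| < 2``; the four
    weights at any sampling phase sum to 1.
    """
    x = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    near = x <= 1
    out[near] = (a + 2) * x[near] ** 3 - (a + 3) * x[near] ** 2 + 1
    far = (x > 1) & (x < 2)
    out[far] = a * x[far] ** 3 - 5 * a * x[far] ** 2 + 8 * a * x[far] - 4 * a
    return out


def _reflect_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror out-of-range indices about the array edges (no edge repeat)."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def _cubic_weight_matrix(n_src: int, n_out: int, scale: float, a: float) -> np.ndarray:
    """Dense (n_out, n_src) matrix of Keys weights along one axis.

    Output sample ``i`` sits at source coordinate ``(i + 0.5) * scale - 0.5``
    (pixel-is-area convention, shared map extent).
    """
    coords = (np.arange(n_out) + 0.5) * scale - 0.5
    base = np.floor(coords).astype(int)
    frac = coords - base
    W = np.zeros((n_out, n_src))
    rows = np.arange(n_out)
    for k in range(-1, 3):
        w = keys_kernel(frac - k, a=a)
        src = _reflect_index(base + k, n_src)
        np.add.at(W, (rows, src), w)
    return W


def resample_cubic(
    raster: MultibandRaster, target_pixel_size: float, a: float = -0.5
) -> MultibandRaster:
    """Resample to a new pixel size by separable cubic convolution.

    The output grid covers the same map extent; each output value is the
    4x4-neighbourhood Keys-kernel weighted average of the source, with
    reflect padding at the borders.  Constant rasters are preserved exactly
    and linear/quadratic ramps are reproduced at interior pixels.
    """
    if not target_pixel_size > 0:
        raise ValidationError("target_pixel_size must be > 0")
    _, rows, cols = raster.shape
    scale = target_pixel_size / raster.pixel_size
    out_rows = int(round(rows / scale))
    out_cols = int(round(cols / scale))
    if out_rows < 1 or out_cols < 1:
        raise ValidationError(
            f"degenerate extent {out_rows}x{out_cols} after resampling"
        )
    Wr = _cubic_weight_matrix(rows, out_rows, scale, a)
    Wc = _cubic_weight_matrix(cols, out_cols, scale, a)
    out = np.einsum("ir,brc,jc->bij", Wr, raster.values.astype(float), Wc,
                    optimize=True)
    bands = [
        BandMeta(b.band_id, b.role, b.center_wavelength, target_pixel_size)
        for b in raster.bands
    ]
    return MultibandRaster(
        values=out,
        bands=bands,
        pixel_size=target_pixel_size,
        origin=raster.origin,
        nodata=raster.nodata,
    )


def percentile_stretch(
    band: np.ndarray, lo: float = 2.0, hi: float = 98.0
) -> np.ndarray:
    """Linearly stretch a band so the [lo, hi] percentiles map to [0, 1]."""
    finite = band[np.isfinite(band)]
    if finite.size == 0:
        raise ValidationError("band has no finite values to stretch")
    vlo, vhi = np.percentile(finite, [lo, hi])
    if vhi <= vlo:
        return np.zeros_like(band, dtype=float)
    return np.clip((band - vlo) / (vhi - vlo), 0.0, 1.0)


def false_color_composite(
    raster: MultibandRaster, percentiles: tuple[float, float] = (2.0, 98.0)
) -> np.ndarray:
    """NIR/red/green false-colour display image, shape (rows, cols, 3).

    Healthy vegetation (high NIR) renders red-dominant.  Each channel is
    independently percentile-stretched to [0, 1]; purely cosmetic.
    """
    channels = []
    for role in ("nir", "red", "green"):
        band = band_by_role(raster, role)  # raises RoleLookupError if absent
        channels.append(percentile_stretch(band, *percentiles))
    return np.stack(channels, axis=-1)
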
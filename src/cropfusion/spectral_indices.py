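"""Per-pixel vegetation indices.

NDVI = (NIR - Red) / (NIR + Red)
EVI  = G * (NIR - Red) / (NIR + C1 * Red - C2 * Blue + L)

with the canonical gain and correction terms G = 2.5, C1 = 6, C2 = 7.5,
L = 1 (aerosol and canopy-background corrections).  Indices are computed on
reflectance grids; out-of-range reflectance (pan-sharpening overshoot) is
clipped to [0, 1] first.  Pixels whose denominator vanishes are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .raster_model import MultibandRaster, band_by_role

__all__ = ["EVIConstants", "ndvi", "evi", "index_stack"]


@dataclass(frozen=True)
class EVIConstants:
    """Gain and correction coefficients of the enhanced vegetation index."""

    G: float = 2.5
    C1: float = 6.0
    C2: float = 7.5
    L: float = 1.0


def _check_shapes(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValidationError(f"grids must be co-registered; got shapes {shapes}")


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index, in [-1, 1] where defined."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    _check_shapes(nir, red)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / np.where(denom != 0, denom, 1.0),
                       np.nan)
    return out


def evi(
    nir: np.ndarray,
    red: np.ndarray,
    blue: np.ndarray,
    constants: EVIConstants = EVIConstants(),
) -> np.ndarray:
    """Enhanced vegetation index; NaN where the denominator is ~0."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    _check_shapes(nir, red, blue)
    denom = nir + constants.C1 * red - constants.C2 * blue + constants.L
    ok = np.abs(denom) >= 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            ok, constants.G * (nir - red) / np.where(ok, denom, 1.0), np.nan
        )
    return out


def index_stack(
    raster: MultibandRaster,
    constants: EVIConstants = EVIConstants(),
    clip_reflectance: bool = True,
) -> dict[str, np.ndarray]:
    """NDVI and EVI grids from a raster with blue/red/nir roles.

    Reflectance is clipped to [0, 1] before computation when
    ``clip_reflectance`` is set (sharpening can overshoot slightly).
    """
    grids = {role: band_by_role(raster, role) for role in ("nir", "red", "blue")}
    if clip_reflectance:
        grids = {k: np.clip(v, 0.0, 1.0) for k, v in grids.items()}
    return {
        "NDVI": ndvi(grids["nir"], grids["red"]),
        "EVI": evi(grids["nir"], grids["red"], grids["blue"], constants),
    }
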
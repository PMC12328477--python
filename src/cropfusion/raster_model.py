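"""Core raster data model and file I/O.

A :class:`MultibandRaster` is the currency of every image-processing stage:
a ``[band, row, col]`` grid of reflectance (float, typically in [0, 1] after
preprocessing) or raw digital numbers, together with per-band metadata.

Two on-disk containers are supported:

* ``.npz`` — a plain NumPy archive plus a JSON sidecar (``<path>.meta.json``)
  carrying band metadata. This is the fixture dialect used by the test suite;
  it needs no geospatial system libraries.
* ``.tif`` / ``.tiff`` — a multiband TIFF written through :mod:`tifffile`,
  with the same JSON sidecar (plain TIFF containers have no band-role tags).

Coordinate convention: row-major, origin at the outer corner of the top-left
pixel, pixel-is-area; the map coordinate of pixel ``(row, col)`` is
``origin + ((col + 0.5) * pixel_size, -(row + 0.5) * pixel_size)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import RasterFormatError, RoleLookupError, ValidationError

__all__ = [
    "BAND_ROLES",
    "BandMeta",
    "MultibandRaster",
    "LabelRaster",
    "band_by_role",
    "read_raster",
    "write_raster",
    "read_labels",
    "write_labels",
]

#: Recognised band roles.  ``pan`` is the panchromatic band.
BAND_ROLES = (
    "blue",
    "green",
    "red",
    "red_edge",
    "nir",
    "nir_narrow",
    "swir1",
    "swir2",
    "pan",
)

#: Roles that may appear at most once per raster.
_UNIQUE_ROLES = {"blue", "red", "nir", "pan"}


@dataclass(frozen=True)
class BandMeta:
    """Metadata for one spectral band.

    Parameters
    ----------
    band_id:
        Short identifier, e.g. ``"B4"`` or ``"band8"``.
    role:
        Spectral role, one of :data:`BAND_ROLES`.
    center_wavelength:
        Band centre in nanometres (> 0).
    native_resolution:
        Ground sampling distance of the source sensor in metres (> 0).
    """

    band_id: str
    role: str
    center_wavelength: float
    native_resolution: float

    def __post_init__(self) -> None:
        if self.role not in BAND_ROLES:
            raise ValidationError(
                f"unknown band role {self.role!r}; expected one of {BAND_ROLES}"
            )
        if not self.center_wavelength > 0:
            raise ValidationError("center_wavelength must be > 0")
        if not self.native_resolution > 0:
            raise ValidationError("native_resolution must be > 0")

    def to_dict(self) -> dict:
        return {
            "band_id": self.band_id,
            "role": self.role,
            "center_wavelength": self.center_wavelength,
            "native_resolution": self.native_resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandMeta":
        return cls(
            band_id=d["band_id"],
            role=d["role"],
            center_wavelength=float(d["center_wavelength"]),
            native_resolution=float(d["native_resolution"]),
        )


@dataclass
class MultibandRaster:
    """A georeferenced multiband grid.

    ``values`` has shape ``(n_bands, rows, cols)``.  ``nodata`` is a sentinel
    value (NaN by default); nodata pixels are excluded from statistics and
    propagate through per-pixel operations.
    """

    values: np.ndarray
    bands: list[BandMeta]
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(
                f"values must be 3-D (band, row, col); got shape {self.values.shape}"
            )
        if len(self.bands) == 0:
            raise ValidationError("band list must not be empty")
        if len(self.bands) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.bands)} BandMeta entries for {self.values.shape[0]} bands"
            )
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        seen: set[str] = set()
        for bm in self.bands:
            if bm.role in _UNIQUE_ROLES and bm.role in seen:
                raise ValidationError(f"duplicate band role {bm.role!r}")
            seen.add(bm.role)

    # -- basic geometry -----------------------------------------------------

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(b.role for b in self.bands)

    # -- nodata handling ----------------------------------------------------

    def valid_mask(self, band_index: int | None = None) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels per band or for one band."""
        arr = self.values if band_index is None else self.values[band_index]
        if self.nodata is None:
            return np.ones(arr.shape, dtype=bool)
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(arr)
        return arr != self.nodata

    def with_values(self, values: np.ndarray) -> "MultibandRaster":
        """Copy of this raster with replaced pixel values (same metadata)."""
        return replace(self, values=np.asarray(values), bands=list(self.bands))


@dataclass
class LabelRaster:
    """Ground-truth class codes on the same pixel grid as a paired raster.

    Codes: 0 = background, 1 = wheat, 2 = maize.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    CLASS_NAMES = {0: "background", 1: "wheat", 2: "maize"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("label grid must be 2-D")
        bad = np.setdiff1d(np.unique(self.values), [0, 1, 2])
        if bad.size:
            raise ValidationError(f"label codes must be in {{0,1,2}}; found {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def band_by_role(raster: MultibandRaster, role: str) -> np.ndarray:
    """Return the single 2-D band grid with the given role.

    Raises
    ------
    RoleLookupError
        If the role is not declared on the raster.
    """
    for bm, band in zip(raster.bands, raster.values):
        if bm.role == role:
            return band
    raise RoleLookupError(
        f"role {role!r} not present; raster declares {list(raster.roles)}"
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _meta_dict(raster: MultibandRaster) -> dict:
    return {
        "bands": [b.to_dict() for b in raster.bands],
        "pixel_size": raster.pixel_size,
        "origin": list(raster.origin),
        "nodata": None
        if raster.nodata is None
        else ("nan" if math.isnan(raster.nodata) else raster.nodata),
    }


def _meta_from_dict(d: dict) -> dict:
    nodata = d.get("nodata")
    if nodata == "nan":
        nodata = float("nan")
    return {
        "bands": [BandMeta.from_dict(b) for b in d["bands"]],
        "pixel_size": float(d["pixel_size"]),
        "origin": tuple(float(v) for v in d["origin"]),
        "nodata": nodata,
    }


def write_raster(raster: MultibandRaster, path: str | Path) -> None:
    """Write a raster plus its JSON band-metadata sidecar.

    The container is chosen from the suffix: ``.npz`` (NumPy archive) or
    ``.tif``/``.tiff`` (multiband TIFF via tifffile).  Values round-trip
    bit-identically through :func:`read_raster`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".npz":
            np.savez(path, values=raster.values)
        elif suffix in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, raster.values, photometric="minisblack")
        else:
            raise RasterFormatError(
                f"unsupported raster container {suffix!r}; use .npz or .tif"
            )
        _sidecar_path(path).write_text(json.dumps(_meta_dict(raster), indent=1))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise RasterFormatError(f"cannot write raster to {path}: {exc}") from exc


def read_raster(path: str | Path) -> MultibandRaster:
    """Read a raster written by :func:`write_raster`.

    Raises
    ------
    RasterFormatError
        For unreadable files or a band-count mismatch between the pixel
        container and the sidecar metadata.
    """
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such raster file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RasterFormatError(f"missing metadata sidecar: {sidecar}")
    suffix = path.suffix.lower()
    try:
        if suffix == ".npz":
            with np.load(path) as npz:
                values = npz["values"]
        elif suffix in (".tif", ".tiff"):
            import tifffile

            values = tifffile.imread(path)
            if values.ndim == 2:
                values = values[None]
        else:
            raise RasterFormatError(f"unsupported raster container {suffix!r}")
        meta = _meta_from_dict(json.loads(sidecar.read_text()))
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise RasterFormatError(f"cannot read raster {path}: {exc}") from exc
    if values.ndim != 3 or len(meta["bands"]) != values.shape[0]:
        raise RasterFormatError(
            f"{path}: {values.shape[0] if values.ndim == 3 else '?'} bands in file "
            f"but sidecar lists {len(meta['bands'])}"
        )
    return MultibandRaster(values=values, **meta)


def write_labels(labels: LabelRaster, path: str | Path) -> None:
    """Write a label raster as ``.npz`` with a small JSON sidecar."""
    path = Path(path)
    np.savez(path, values=labels.values.astype(np.int16))
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size": labels.pixel_size, "origin": list(labels.origin)})
    )


def read_labels(path: str | Path) -> LabelRaster:
    """Read a label raster written by :func:`write_labels`."""
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such label file: {path}")
    with np.load(path) as npz:
        values = npz["values"]
    meta = json.loads(_sidecar_path(path).read_text())
    return LabelRaster(
        values=values,
        pixel_size=float(meta["pixel_size"]),
        origin=tuple(meta["origin"]),
    )


def make_bands(roles: Sequence[str], resolution: float = 10.0) -> list[BandMeta]:
    """Convenience constructor: plausible band metadata for the given roles.

    Centre wavelengths follow typical Sentinel-2A / Landsat 8-9 band centres.
    """
    centers = {
        "blue": 490.0,
        "green": 560.0,
        "red": 665.0,
        "red_edge": 705.0,
        "nir": 842.0,
        "nir_narrow": 865.0,
        "swir1": 1610.0,
        "swir2": 2190.0,
        "pan": 590.0,
    }
    return [
        BandMeta(band_id=f"B{i}", role=r, center_wavelength=centers[r],
                 native_resolution=resolution)
        for i, r in enumerate(roles)
    ]
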
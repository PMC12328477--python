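"""Gram-Schmidt pan-sharpening.

The transform builds a simulated panchromatic band as the unweighted
pixel-wise mean of the multispectral bands, then sequentially orthogonalises
each (mean-centred) band against the simulated pan and all previously
produced components.  Sharpening substitutes a histogram-matched real pan
band for component 0 and inverts the transform, injecting the pan's high
spatial frequencies while preserving each band's global mean (the affine
histogram match equates first and second moments with the simulated pan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .preprocess import resample_cubic
from .raster_model import MultibandRaster

__all__ = [
    "GSModel",
    "simulate_pan",
    "gs_forward",
    "gs_inverse",
    "histogram_match",
    "gs_pansharpen",
]


@dataclass
class GSModel:
    """Fitted Gram-Schmidt transform.

    ``gs_coefficients[k][l]`` is the projection coefficient of band ``k``
    onto component ``l`` (``l <= k``), forming a lower-triangular system;
    inversion with the untouched component stack reproduces the input
    exactly up to floating-point error.
    """

    simulated_pan: np.ndarray
    gs_coefficients: list[list[float]]
    band_means: np.ndarray
    pan_match: tuple[float, float] | None = None  # (gain, offset)


def simulate_pan(ms: MultibandRaster) -> np.ndarray:
    """Pixel-wise unweighted mean across bands; NaN where any band is nodata."""
    if ms.n_bands < 2:
        raise ValidationError("simulated pan needs at least 2 bands")
    values = ms.values.astype(float).copy()
    invalid = ~ms.valid_mask()
    if invalid.any():
        values[invalid] = np.nan
    return values.mean(axis=0)


def gs_forward(ms: MultibandRaster) -> tuple[GSModel, np.ndarray]:
    """Forward Gram-Schmidt transform.

    Returns the fitted model and the component stack of shape
    ``(n_bands + 1, rows, cols)``: component 0 is the simulated pan, and
    component ``k`` (k >= 1) is the residual of mean-centred band ``k - 1``
    after projecting out components ``0 .. k-1``.
    """
    sim_pan = simulate_pan(ms)
    if np.nanstd(sim_pan) == 0:
        raise DegenerateInputError("simulated pan has zero variance")
    n_bands, rows, cols = ms.shape
    band_means = ms.values.reshape(n_bands, -1).mean(axis=1)

    comps = np.empty((n_bands + 1, rows, cols))
    comps[0] = sim_pan - sim_pan.mean()
    coeffs: list[list[float]] = []
    flat = lambda g: g.reshape(-1)  # noqa: E731
    for k in range(n_bands):
        band = ms.values[k].astype(float) - band_means[k]
        ck: list[float] = []
        resid = flat(band).copy()
        for l in range(k + 1):
            comp = flat(comps[l])
            denom = comp @ comp
            phi = 0.0 if denom == 0 else float(resid @ comp) / denom
            resid -= phi * comp
            ck.append(phi)
        comps[k + 1] = resid.reshape(rows, cols)
        coeffs.append(ck)
    model = GSModel(
        simulated_pan=sim_pan, gs_coefficients=coeffs, band_means=band_means
    )
    return model, comps


def gs_inverse(model: GSModel, comps: np.ndarray, ms_template: MultibandRaster
               ) -> MultibandRaster:
    """Invert the transform: rebuild bands from a (possibly edited) stack."""
    n_bands = len(model.gs_coefficients)
    if comps.shape[0] != n_bands + 1:
        raise ValidationError(
            f"component stack has {comps.shape[0]} layers; expected {n_bands + 1}"
        )
    out = np.empty((n_bands,) + comps.shape[1:])
    for k, ck in enumerate(model.gs_coefficients):
        band = comps[k + 1].copy()
        for l, phi in enumerate(ck):
            band += phi * comps[l]
        out[k] = band + model.band_means[k]
    return ms_template.with_values(out)


def histogram_match(source: np.ndarray, reference: np.ndarray
                    ) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine match of ``source`` to the mean/stddev of ``reference``.

    Returns the matched grid and the (gain, offset) applied.
    """
    s_std = float(np.nanstd(source))
    if s_std == 0:
        raise DegenerateInputError("pan band has zero variance")
    gain = float(np.nanstd(reference)) / s_std
    offset = float(np.nanmean(reference)) - gain * float(np.nanmean(source))
    return gain * source + offset, (gain, offset)


def gs_pansharpen(
    ms_low: MultibandRaster, pan_high: np.ndarray, pan_pixel_size: float | None = None
) -> MultibandRaster:
    """Sharpen a low-resolution multispectral stack with a high-res pan band.

    Steps: (1) upsample ``ms_low`` to the pan grid by cubic convolution,
    (2) forward Gram-Schmidt, (3) histogram-match the real pan to the
    simulated pan, (4) substitute the matched pan for component 0,
    (5) invert.  The result has the pan grid's resolution and ``ms_low``'s
    band count, with per-band global means preserved.
    """
    pan_high = np.asarray(pan_high, dtype=float)
    if pan_high.ndim != 2:
        raise ValidationError("pan band must be a 2-D grid")
    _, rows, cols = ms_low.shape
    ratio = 1
    if (rows, cols) == pan_high.shape:
        ms_up = ms_low
    else:
        if pan_high.shape[0] % rows or pan_high.shape[1] % cols:
            raise ValidationError(
                f"pan grid {pan_high.shape} is not an integer multiple of the "
                f"multispectral grid {(rows, cols)}"
            )
        ratio = pan_high.shape[0] // rows
        if pan_high.shape[1] // cols != ratio:
            raise ValidationError("pan/MS resolution ratio differs between axes")
        target = (
            pan_pixel_size if pan_pixel_size is not None
            else ms_low.pixel_size / ratio
        )
        ms_up = resample_cubic(ms_low, target)
        if ms_up.shape[1:] != pan_high.shape:
            raise ValidationError(
                f"upsampled grid {ms_up.shape[1:]} does not match pan {pan_high.shape}"
            )
    model, comps = gs_forward(ms_up)
    if ratio > 1:
        # Estimate the matching gain at the resolution where pan and MS are
        # commensurate: degrading the pan to the MS grid avoids the variance
        # loss the upsampled simulated pan suffers, which would otherwise
        # leak a radiometric bias into every band.  The offset anchors the
        # matched pan to the simulated pan's mean, preserving band means.
        from .synthetic_scene import block_mean

        pan_low_std = float(np.nanstd(block_mean(pan_high, ratio)))
        if pan_low_std == 0:
            raise DegenerateInputError("pan band has zero variance")
        gain = float(np.nanstd(block_mean(model.simulated_pan, ratio))) / pan_low_std
        offset = float(np.nanmean(model.simulated_pan)) - gain * float(
            np.nanmean(pan_high)
        )
        matched = gain * pan_high + offset
        model.pan_match = (gain, offset)
    else:
        matched, model.pan_match = histogram_match(pan_high, model.simulated_pan)
    comps = comps.copy()
    comps[0] = matched - model.simulated_pan.mean()
    return gs_inverse(model, comps, ms_up)
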
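"""Multi-patch GLCM texture features.

A gray-level co-occurrence matrix (GLCM) tallies how often pairs of
quantized gray levels co-occur at a fixed pixel offset.  Texture is
characterised by four scalars of the normalized symmetric matrix
``P(i, j)``:

* correlation  ``sum (i - mu)(j - nu) P(i,j) / (sigma_i sigma_j)``
* contrast     ``sum (i - j)^2 P(i,j)``
* energy       ``sum P(i,j)^2``  (angular second moment)
* entropy      ``-sum P(i,j) ln P(i,j)``  (0 ln 0 := 0)

The multi-patch extractor slides a window across the image, quantizes each
window locally, computes one GLCM per orientation (0, 45, 90, 135 degrees
by default) and aggregates the per-orientation features (arithmetic mean by
default), yielding feature maps co-registered with the input band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "GLCMConfig",
    "GLCMMatrix",
    "TextureFeatures",
    "FEATURE_NAMES",
    "quantize",
    "glcm",
    "glcm_features",
    "multipatch_texture",
]

FEATURE_NAMES = ("correlation", "contrast", "energy", "entropy")

#: Relative range below which a window counts as constant during
#: quantization (keeps numerical dust from becoming full-range texture).
_CONSTANT_EPS = 1e-9

# Pixel offsets (row, col) per orientation, distance 1; up-right is 45 deg.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Configuration of the sliding-window texture extractor.

    ``degenerate_correlation`` is the value reported when a window has zero
    marginal variance (a constant patch); 1.0 by convention — a constant
    patch is perfectly self-correlated — configurable to 0.
    """

    window: int = 15
    levels: int = 32
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    stride: int = 1
    padding: str = "reflect"
    aggregate: str = "mean"
    degenerate_correlation: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if self.distance < 1:
            raise ValidationError("distance must be >= 1")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        unknown = set(self.angles) - set(_ANGLE_OFFSETS)
        if unknown:
            raise ValidationError(f"unsupported angles {sorted(unknown)}")
        if self.aggregate not in ("mean", "max", "min"):
            raise ValidationError("aggregate must be one of mean/max/min")


@dataclass
class GLCMMatrix:
    """Normalized symmetric co-occurrence matrix with its marginal moments."""

    P: np.ndarray
    levels: int
    mu_i: float = field(init=False)
    mu_j: float = field(init=False)
    sigma_i: float = field(init=False)
    sigma_j: float = field(init=False)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.levels, self.levels):
            raise ValidationError("P must be levels x levels")
        if (self.P < 0).any():
            raise ValidationError("P entries must be >= 0")
        if not math.isclose(self.P.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("P must sum to 1")
        idx = np.arange(self.levels, dtype=float)
        p_i = self.P.sum(axis=1)
        p_j = self.P.sum(axis=0)
        self.mu_i = float(p_i @ idx)
        self.mu_j = float(p_j @ idx)
        self.sigma_i = float(math.sqrt(max(p_i @ idx**2 - self.mu_i**2, 0.0)))
        self.sigma_j = float(math.sqrt(max(p_j @ idx**2 - self.mu_j**2, 0.0)))


@dataclass(frozen=True)
class TextureFeatures:
    correlation: float
    contrast: float
    energy: float
    entropy: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.correlation, self.contrast, self.energy, self.entropy)


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin a band into integer gray levels ``0 .. levels - 1``.

    Binning spans the band's valid (finite) min-max range; a band that is
    constant (up to a relative epsilon, so floating-point dust is not
    stretched into fake texture) maps to level 0.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    band = np.asarray(band, dtype=float)
    finite = np.isfinite(band)
    if not finite.any():
        raise ValidationError("band has no valid values")
    vmin = band[finite].min()
    vmax = band[finite].max()
    out = np.zeros(band.shape, dtype=np.int64)
    if vmax - vmin > _CONSTANT_EPS * max(abs(vmin), abs(vmax)):
        scaled = (band[finite] - vmin) / (vmax - vmin) * levels
        out[finite] = np.minimum(scaled.astype(np.int64), levels - 1)
    return out


def glcm(patch: np.ndarray, angle: int, distance: int = 1, levels: int = 32
         ) -> GLCMMatrix:
    """Co-occurrence matrix of one integer patch at one orientation.

    Pairs are counted in both directions (symmetrized) and normalized to
    sum 1.
    """
    patch = np.asarray(patch)
    if angle not in _ANGLE_OFFSETS:
        raise ValidationError(f"unsupported angle {angle}")
    if patch.min() < 0 or patch.max() >= levels:
        raise ValidationError("patch values must lie in [0, levels - 1]")
    dr, dc = (d * distance for d in _ANGLE_OFFSETS[angle])
    rows, cols = patch.shape
    r0 = max(0, -dr)
    r1 = rows - max(0, dr)
    c0 = max(0, -dc)
    c1 = cols - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError("patch too small for this offset: no pairs")
    a = patch[r0:r1, c0:c1].ravel()
    b = patch[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(
        levels, levels
    ).astype(float)
    counts += counts.T  # symmetrize
    return GLCMMatrix(P=counts / counts.sum(), levels=levels)


def glcm_features(M: GLCMMatrix, degenerate_correlation: float = 1.0
                  ) -> TextureFeatures:
    """The four texture scalars of one GLCM (natural-log entropy)."""
    N = M.levels
    idx = np.arange(N, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    P = M.P
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P**2).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    if M.sigma_i == 0 or M.sigma_j == 0:
        correlation = degenerate_correlation
    else:
        correlation = float(
            (((i - M.mu_i) * (j - M.mu_j) * P).sum()) / (M.sigma_i * M.sigma_j)
        )
    return TextureFeatures(correlation, contrast, energy, entropy)


# ---------------------------------------------------------------------------
# Sliding-window (multi-patch) extraction
# ---------------------------------------------------------------------------


def _window_features(
    q: np.ndarray, offsets: list[tuple[int, int]], win: int, N: int,
    degenerate_correlation: float,
) -> np.ndarray:
    """Per-angle features for a block of quantized windows.

    ``q``: (n_windows, win*win) integer gray levels.  Returns an array of
    shape (n_angles, n_windows, 4) ordered per :data:`FEATURE_NAMES`.
    """
    n_win = q.shape[0]
    idx = np.arange(N, dtype=float)
    i_grid = np.repeat(idx, N)
    j_grid = np.tile(idx, N)
    sq_diff = (i_grid - j_grid) ** 2
    prod_ij = i_grid * j_grid
    out = np.empty((len(offsets), n_win, 4))
    pos = np.arange(win * win).reshape(win, win)
    for a, (dr, dc) in enumerate(offsets):
        r0, r1 = max(0, -dr), win - max(0, dr)
        c0, c1 = max(0, -dc), win - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            raise DegenerateInputError("window too small for this offset")
        src = pos[r0:r1, c0:c1].ravel()
        dst = pos[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        ca = q[:, src]
        cb = q[:, dst]
        # count both directions: symmetric GLCM; every window has the same
        # pair total, so normalization is by the scalar ``tot``
        codes = np.concatenate([ca * N + cb, cb * N + ca], axis=1)
        win_idx = np.repeat(np.arange(n_win), codes.shape[1])
        counts = np.bincount(
            (win_idx * (N * N) + codes.ravel()), minlength=n_win * N * N
        ).reshape(n_win, N * N).astype(float)
        tot = float(codes.shape[1])
        contrast = (counts @ sq_diff) / tot
        energy = (counts * counts).sum(axis=1) / tot**2
        # entropy from nonzero counts only (the matrix is sparse):
        # -sum p ln p = ln(tot) - (1/tot) sum c ln c
        nz = counts > 0
        clogc = np.zeros(counts.shape)
        cvals = counts[nz]
        clogc[nz] = cvals * np.log(cvals)
        entropy = np.log(tot) - clogc.sum(axis=1) / tot
        Cm = counts.reshape(n_win, N, N)
        c_i = Cm.sum(axis=2)
        c_j = Cm.sum(axis=1)
        mu_i = (c_i @ idx) / tot
        mu_j = (c_j @ idx) / tot
        var_i = (c_i @ idx**2) / tot - mu_i**2
        var_j = (c_j @ idx**2) / tot - mu_j**2
        e_ij = (counts @ prod_ij) / tot
        sig = np.sqrt(np.clip(var_i, 0, None) * np.clip(var_j, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(
                sig > 0, (e_ij - mu_i * mu_j) / np.where(sig > 0, sig, 1.0),
                degenerate_correlation,
            )
        out[a, :, 0] = corr
        out[a, :, 1] = contrast
        out[a, :, 2] = energy
        out[a, :, 3] = entropy
    return out


def multipatch_texture(
    band: np.ndarray, config: GLCMConfig | None = None
) -> dict[str, np.ndarray]:
    """Sliding-window texture feature maps for one band.

    Every output position carries the orientation-aggregated correlation,
    contrast, energy and entropy of the locally quantized window centred
    there.  With the default stride 1 and reflect padding the maps are
    pixel-co-registered with the input band.

    Returns
    -------
    dict
        ``{"correlation": map, "contrast": map, "energy": map, "entropy": map}``.
    """
    if config is None:
        config = GLCMConfig()
    band = np.asarray(band, dtype=float)
    if band.ndim != 2:
        raise ValidationError("band must be 2-D")
    win = config.window
    half = win // 2
    if config.padding == "none":
        padded = band
    else:
        padded = np.pad(band, half, mode=config.padding)
    if padded.shape[0] < win or padded.shape[1] < win:
        raise ValidationError(
            f"window {win} larger than padded band {padded.shape}"
        )
    windows = sliding_window_view(padded, (win, win))[
        ::config.stride, ::config.stride
    ]
    out_shape = windows.shape[:2]
    flat = windows.reshape(-1, win * win)

    # local per-window quantization (same constancy guard as `quantize`)
    N = config.levels
    wmin = flat.min(axis=1, keepdims=True)
    wmax = flat.max(axis=1, keepdims=True)
    rng = wmax - wmin
    constant = rng <= _CONSTANT_EPS * np.maximum(np.abs(wmin), np.abs(wmax))
    safe_rng = np.where(constant, 1.0, rng)
    q = np.minimum(((flat - wmin) / safe_rng * N).astype(np.int64), N - 1)
    q[constant.ravel()] = 0

    offsets = [
        tuple(d * config.distance for d in _ANGLE_OFFSETS[a])
        for a in config.angles
    ]
    n_win = q.shape[0]
    chunk = max(1, (1 << 22) // (N * N))
    feats = np.empty((len(offsets), n_win, 4))
    for start in range(0, n_win, chunk):
        stop = min(start + chunk, n_win)
        feats[:, start:stop] = _window_features(
            q[start:stop], offsets, win, N, config.degenerate_correlation
        )
    if config.aggregate == "mean":
        agg = feats.mean(axis=0)
    elif config.aggregate == "max":
        agg = feats.max(axis=0)
    else:
        agg = feats.min(axis=0)
    return {
        name: agg[:, k].reshape(out_shape)
        for k, name in enumerate(FEATURE_NAMES)
    }
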
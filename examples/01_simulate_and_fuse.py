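"""Generate a synthetic paired scene and pan-sharpen it.

Builds a late-season (T4) wheat/maize scene at two resolutions, fuses the
coarse six-band stack with the fine panchromatic band by Gram-Schmidt
substitution, and prints the invariants that make the fusion trustworthy:
exact inversion, preserved band means, and injected spatial detail.
"""

import numpy as np
from scipy import ndimage

from cropfusion import (
    SceneConfig,
    band_by_role,
    generate_scene,
    gs_pansharpen,
    resample_cubic,
)

scene = generate_scene(SceneConfig(seed=42), "T4")
print(f"hires stack : {scene.hires_ms.shape} at {scene.hires_ms.pixel_size} m")
print(f"lores stack : {scene.lores_ms.shape} at {scene.lores_ms.pixel_size} m")
print(f"pan band    : {scene.pan.shape} at {scene.hires_ms.pixel_size} m")

fused = gs_pansharpen(scene.lores_ms, scene.pan)
up = resample_cubic(scene.lores_ms, scene.hires_ms.pixel_size)

drift = np.abs(fused.values.mean(axis=(1, 2)) - up.values.mean(axis=(1, 2)))
print(f"\nfused stack : {fused.shape} at {fused.pixel_size} m")
print(f"max per-band mean drift vs upsampled input: {drift.max():.2e}")

sharp = ndimage.laplace(band_by_role(fused, "nir")).var()
smooth = ndimage.laplace(band_by_role(up, "nir")).var()
print(f"NIR Laplacian variance, fused vs plain upsampling: "
      f"{sharp:.2e} vs {smooth:.2e}")
print("\nThe mean drift near machine precision shows the sharpening is "
      "radiometrically neutral; the larger Laplacian variance shows the pan "
      "band's spatial detail was injected into every spectral band.")
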
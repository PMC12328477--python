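"""Extract the six per-pixel features from a fused scene.

Computes NDVI/EVI and the four sliding-window GLCM texture statistics on
the fused NIR band, then prints per-class means: the spectral gap between
wheat and maize and the texture contrast between their canopies are what
the downstream classifier learns from.
"""

import numpy as np

from cropfusion import SceneConfig, generate_scene, scene_features

scene = generate_scene(SceneConfig(seed=42), "T4")
maps, fused = scene_features(scene, window=15, levels=32)

labels = scene.labels.values
print(f"{'feature':12s} {'wheat':>8s} {'maize':>8s} {'background':>11s}")
for name, grid in maps.items():
    row = [np.nanmean(grid[labels == code]) for code in (1, 2, 0)]
    print(f"{name:12s} {row[0]:8.3f} {row[1]:8.3f} {row[2]:11.3f}")

gap = (np.nanmean(maps["NDVI"][labels == 1])
       - np.nanmean(maps["NDVI"][labels == 2]))
print(f"\nwheat-maize NDVI gap at T4: {gap:.3f}")
print("At T4 (late March) wheat is near its canopy peak while maize has "
      "barely emerged, so the NDVI gap is wide; the GLCM statistics differ "
      "because the two canopies carry different spatial correlation lengths.")
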
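# cropfusion

Early-stage crop classification from fused satellite imagery.

Wheat and maize are nearly indistinguishable in their first weeks: their
spectra and canopy textures overlap, and neither a single sensor's spectral
bands nor its spatial resolution is sufficient on its own. `cropfusion`
implements a fusion-based pipeline for this problem, aimed at remote-sensing
practitioners and method developers: it merges a fine-resolution
multispectral stack (Sentinel-2A-like, 10 m) with a coarser stack carrying a
panchromatic band (Landsat 8–9-like, 30 m / 15 m pan), extracts spectral and
textural features from the fused image over a five-interval time series
(T1–T5, December through April), balances the two feature groups, and trains
and scores a configurable set of classifiers. Because no public scene pair
with ground truth exists for this setting, the package ships a synthetic
paired-scene generator with a controllable wheat/maize separability
schedule, so the entire pipeline is runnable and testable offline.

## Method

**Gram-Schmidt pan-sharpening.** A simulated panchromatic band is the
unweighted band mean `P̂ = (1/B) Σ_b M_b`. Each mean-centred band is
sequentially orthogonalised against `P̂` and all previous components
(coefficients `φ_kl = ⟨M_k, GS_l⟩ / ⟨GS_l, GS_l⟩`, a lower-triangular
system). The real pan is matched to `P̂`'s first two moments, substituted
for component 0, and the transform inverted — injecting the pan's spatial
detail while preserving every band's global mean.

**Multi-patch GLCM texture.** In a sliding window (default 15×15, 32 gray
levels, offset distance 1), the normalized symmetric co-occurrence matrix
`P(i,j)` is computed at 0°, 45°, 90° and 135°, and four statistics are
averaged over orientation:

    correlation = Σᵢ Σⱼ (i−μ)(j−ν) P(i,j) / (σᵢ σⱼ)
    contrast    = Σᵢ Σⱼ (i−j)² P(i,j)
    energy      = Σᵢ Σⱼ P(i,j)²
    entropy     = −Σᵢ Σⱼ P(i,j) ln P(i,j)

**Spectral indices.** `NDVI = (NIR−Red)/(NIR+Red)` and
`EVI = 2.5 (NIR−Red)/(NIR + 6 Red − 7.5 Blue + 1)`, computed on the fused
stack.

**Feature Weighting Method (FWM).** Each feature's time profile is
summarised by mean and standard deviation; the standardized distance between
two features is `d = (x̄ᵢ − x̄ⱼ)/(sᵢ + sⱼ)`. The spectral group (EVI, NDVI)
and textural group (correlation, contrast, energy, entropy) receive weights
`w₁, w₂` proportional to their mean absolute standardized distances,
normalized so `w₁ + w₂ = 1`, and the 6-dimensional feature vectors are
rescaled accordingly.

**Classification and evaluation.** Stratified 80:10:10 splits; backends
DNN (ReLU MLP [128, 256, 128]), Conv1D, random forest, decision tree,
RBF-SVM, LightGBM, XGBoost and CatBoost (the boosting backends are optional
plug-ins behind a capability check); binary metrics with wheat as the
positive class: accuracy, precision, recall, F1.

## Worked example

```python
from cropfusion import ClassifierSpec, SceneConfig
from cropfusion.pipeline import time_series_accuracy

table = time_series_accuracy(SceneConfig(seed=42), ClassifierSpec("RF"),
                             seeds=(42,))
print(table.round(3))
```

```
    seed_42   mean
T1    0.765  0.765
T2    0.845  0.845
T3    0.945  0.945
T4    0.990  0.990
T5    0.920  0.920
```

Each row is the held-out accuracy of a random forest trained on that
interval's 2,000 fused-feature vectors. Accuracy rises from T1 (December —
both crops are barely emerged) to T4 (late March — wheat at its canopy
peak), the time-series signature the method is built to exploit, and dips at
T5 as wheat senesces. The `examples/` directory holds one short script per
capability (simulation + fusion, texture/indices, feature weighting,
time-series classification, window sweep + classification map); each prints
its numbers with a line on what they mean. A thin CLI mirrors the stages:
`cropfusion simulate | preprocess | fuse | texture | indices | features |
train | evaluate | sweep-window`.

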
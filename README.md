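# hkls — hybrid K-means + level-set skin-lesion segmentation

`hkls` segments melanocytic skin lesions (nevi and melanomas) in RGB
dermoscopic or standard clinical photographs and returns a binary lesion
mask plus the full set of segmentation agreement statistics. It is aimed
at researchers who need a classical, training-free baseline segmenter
and a reproducible way to benchmark it without downloading clinical
datasets: a seeded synthetic-image generator produces lesion photographs
with ground-truth masks and the usual acquisition artifacts (hair,
vignetting, ruler marks, illumination gradients, sensor noise).

## Method

The pipeline is a hybrid two-stage scheme:

1. **Chromatic preprocessing.** The image is converted to CIE L\*a\*b\*;
   the lightness channel is discarded and the two chromaticity channels
   are histogram-equalized and fused into a scalar substrate
   `gray = (a_eq + b_eq)/2`. Illumination gradients and vignetting live
   mostly in L\*, while melanin contrast survives in chroma, so the
   fusion image is far less sensitive to lighting than raw intensity. A
   5×5 gray-level maximum filter erases thin dark artifacts (hair, ruler
   ticks), and near-black frame pixels are excluded by keeping the
   largest bright blob.
2. **Hierarchical K-means initialization.** Top-down two-level K-means
   (K₁ = 2, then K₂ = 3 inside the darker, lesion-like cluster; 20 Lloyd
   iterations per level, squared-Euclidean distance) yields a coarse
   lesion region R₀.
3. **Distance-regularized level set evolution (DRLSE).** A level-set
   function φ is initialized as a binary step ±c₀ on the margin-expanded
   bounding box of R₀ and evolved by the gradient flow of

   E(φ) = μ R_p(φ) + λ L_g(φ) + α A_g(φ),

   where R_p is the double-well distance-regularization term (which
   keeps |∇φ| ≈ 1 without any reinitialization), L_g the g-weighted
   contour length, A_g the g-weighted area, and
   g = 1/(1 + |∇(G_σ∗I)|²) the edge indicator. Defaults: μ = 0.02,
   λ = 5, ε = 1.5, c₀ = 3, Δt = 8, σ = 1.5, 600 iterations
   (1000 with `--preset nevus`); α = +3 or +5 by an area rule, positive
   so the box shrinks onto the lesion border.
4. **Postprocessing.** Hole filling, 5-px square erosion, Delaunay
   (alpha-shape style) boundary smoothing, largest component.
5. **Evaluation.** Accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity
   = TP/(TP+FN), specificity = TN/(TN+FP), Jaccard, Dice, F-measure,
   symmetric boundary Hausdorff distance (raw pixels and normalized by
   the image diagonal), Bland-Altman bias/limits and OLS regression of
   lesion areas.

See `docs/methods.md` for assumptions, parameter rationale, and known
limitations.

## Worked example

Generate three synthetic lesion images and segment one against its
ground truth:

```bash
$ hkls synth --n 3 --out demo --seed 7
wrote 3 image/mask pairs to demo

$ hkls segment demo/img_001.png --mask demo/mask_001.png --out demo/seg
mask: demo/seg/img_001_mask.png (4029 lesion px, 2.9 s)
dice=0.901 jaccard=0.820 accuracy=0.987
```

The Dice coefficient of 0.901 means the predicted mask overlaps 90% of
the union-average with the true lesion; accuracy counts all pixels,
lesion and background alike. Scoring a directory of predictions adds
study-level area agreement:

```bash
$ hkls evaluate --pred demo/seg --truth demo --out demo/report.csv
      accuracy  sensitivity  specificity   jaccard      dice  f_measure  hausdorff_px  hausdorff_norm
mean  0.983109     0.836983          1.0  0.836983  0.911173   0.911173      5.347340        0.014770
std   0.002960     0.020021          0.0  0.020021  0.011821   0.011821      0.330057        0.000912
area bias -1107.0 ± 194.0 px²; regression slope 0.904, r 0.999
```

The negative area bias reflects the deliberate conservatism of the
final 5-px erosion; the regression slope near 1 and r ≈ 0.999 say the
predicted lesion areas track the true areas almost perfectly. The
cluster-count selection experiment is available as a sweep:

```bash
$ hkls sweep --k1 2,3 --k2 2,3,4,5 --n 5 --out sweep.csv
```

Library use mirrors the CLI:

```python
from hkls import SyntheticSpec, generate_image, segment

img, truth = generate_image(SyntheticSpec(seed=42))
mask, record = segment(img, truth=truth)
print(record.metrics.dice)
```

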
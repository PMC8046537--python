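# Methods

## Problem and model

The package segments a single melanocytic lesion — a darker, pigmented
region — from the surrounding skin in an 8-bit RGB photograph. The
segmentation model is a hybrid of an unsupervised clustering
initializer and a geometric active contour:

- **Fusion substrate.** sRGB is converted to CIE L\*a\*b\* (D65). L\* is
  discarded; a\* and b\* are independently min-max rescaled and
  histogram-equalized (256 bins, discrete CDF mapping, ties broken by
  bin order; a constant channel degenerates to the constant 0.5). The
  3-channel fusion image stacks (a_eq, b_eq, mean) and the scalar
  substrate used for clustering and edge detection is the mean of the
  two equalized channels — a symmetric, parameter-free choice that
  reduces to either channel when they agree. Multiplicative
  illumination changes scale X, Y, Z jointly and enter a\*/b\* only
  through the ~cube-root of the gain, so the substrate is an order of
  magnitude less gain-sensitive than raw intensity; the rank-based
  equalization then restores full contrast regardless of the raw chroma
  amplitude.
- **Artifact suppression.** A 5×5 gray-level maximum filter (dilation)
  on the fusion channels erases dark structures narrower than 5 px
  (hair, ruler ticks) at the cost of eroding the broad dark lesion by
  ≤ 2 px — slack the level set and the binarization threshold largely
  recover. Near-black pixels (luminance < 0.15 of full scale) are
  flagged as frame/vignette; the valid region is the largest
  8-connected bright blob, and excluded pixels are set to the
  valid-region median so they cannot attract centroids. A fully dark
  image keeps all pixels with a warning.
- **Hierarchical K-means.** Lloyd's algorithm (squared-Euclidean,
  k-means++ seeding, 20 iterations per level, empty clusters re-seeded
  to the point farthest from its centroid, per-iteration SSE asserted
  non-increasing) splits the valid pixels' substrate values into K₁ = 2
  clusters; the darker cluster is the lesion candidate and is
  re-clustered with K₂ = 3. Exactly two levels are used; deeper
  recursion is not implemented because the published configuration uses
  two.
- **Sub-cluster selection.** The initial region keeps the candidate's
  sub-clusters whose centroid is closer to the darkest sub-centroid
  than to the background (skin) mean, then takes the largest
  8-connected component and fills holes. Anchoring the cutoff to the
  skin gray is deliberate: when the candidate is a single noisy mode
  its three sub-centroids are roughly evenly spaced, and any cutoff
  near the middle sub-centroid (e.g. the candidate mean) sits on a
  knife edge that can discard two-thirds of the lesion. Ties between
  equal-size components break toward the darker, then top-left-most
  component.
- **DRLSE.** φ is initialized as −c₀ inside the bounding box of the
  initial region expanded by 10 px (+c₀ outside) and evolved by the
  explicit gradient flow

  φ ← φ + Δt·[ μ·div(d_p(|∇φ|)∇φ) + λ·δ_ε(φ)·div(g∇φ/|∇φ|) + α·g·δ_ε(φ) ]

  with the double-well potential p(s) = (1/(2π)²)(1 − cos 2πs) for
  s ≤ 1 and ½(s−1)² for s ≥ 1 (d_p(0) = 1 by the analytic limit), the
  smoothed Dirac δ_ε(x) = (1+cos(πx/ε))/(2ε) on |x| ≤ ε, and the edge
  indicator g = 1/(1+|∇(G_σ∗I)|²). No reinitialization is ever
  performed — the double-well term maintains |∇φ| ≈ 1 in the contour
  band. Spatial discretization is central differences with mirrored
  (Neumann) borders and a 4-neighbor Laplacian in the regularization
  term. A positive α shrinks the enclosed (φ < 0) region, so the
  rectangle collapses onto the lesion edge where g ≈ 0 stops it.
- **Binarization and cleanup.** φ is mapped affinely
  (φ = −c₀ ↦ 255, +c₀ ↦ 0) and thresholded at 80, keeping a ≈ 1.1-px
  band outside the zero level set; then hole filling, binary erosion by
  a 5×5 square (borders count as background; an erosion that would
  empty the mask is skipped with a warning), Delaunay boundary
  smoothing, a final hole fill, and the largest 8-connected component.
  The Delaunay step triangulates the boundary pixels, keeps triangles
  whose longest edge is ≤ L_max = 30 px, and unions them with the input
  (alpha-shape-style regularization: bridges cracks and smooths jagged
  borders). The union with the input is required for correctness — for
  a convex region the boundary points are near-cocircular and the
  long-edged interior triangles are dropped, so the kept triangles
  alone would form only a boundary ring.

## Parameters

| key | default | meaning |
|---|---|---|
| `preprocess.max_filter_size` | 5 px | max-filter window; 0 disables |
| `preprocess.vignette_cutoff` | 0.15 | dark-pixel luminance cutoff (fraction of 255) |
| `preprocess.equalize_bins` | 256 | histogram-equalization bins |
| `preprocess.substrate` | `fusion` | `grayscale` switches to the raw-luminance ablation |
| `hk.k1`, `hk.k2` | 2, 3 | cluster counts per level |
| `hk.max_iter` | 20 | Lloyd iterations per level |
| `hk.split_all` | false | split every level-1 cluster instead of the candidate only |
| `drlse.mu` | 0.02 | distance-regularization weight (μ·Δt < 0.25 required) |
| `drlse.lambda` | 5 | weighted-length weight |
| `drlse.alpha_small/alpha_large` | 3 / 5 | area weight by initial-region size |
| `drlse.area_threshold` | 0.15 | image-area fraction switching α = 3 → 5 |
| `drlse.eps` | 1.5 | Dirac/Heaviside smoothing width (px) |
| `drlse.c0` | 3 | initial LSF magnitude |
| `drlse.dt` | 8 | time step |
| `drlse.sigma` | 1.5 | edge-indicator Gaussian SD (px) |
| `drlse.n_iter` | 600 | iterations (1000 for the nevus preset) |
| `drlse.mask_threshold` | 80 | 8-bit binarization threshold |
| `post.erode_width` | 5 px | erosion square width |
| `post.lmax` | 30 px | Delaunay edge-length cutoff |

Numerical conventions worth noting:

- The edge indicator takes gradients on the 0–255 intensity scale
  (substrate × 255). The weights λ = 5 and α ∈ {3, 5} are calibrated
  for 8-bit gradient magnitudes; on a unit-scale image g ≈ 1 everywhere
  and no edge could stop the contour.
- The α if-then rule uses the initial region's image-area fraction with
  a 0.15 threshold (strict inequality; ties take α = 3): large initial
  boxes get the stronger shrink force.
- Early stopping (on by default) halts the evolution when the enclosed
  region changes by < 5 px² over 50 iterations; all published defaults
  remain available by disabling it.
- The 0.15 vignette cutoff separates true black frames from dark
  lesions on all synthetic fixtures; it is a convention, not a fitted
  value.

## Synthetic data

`hkls.synthetic` renders a perturbed-ellipse lesion (smooth periodic
radial perturbation, amplitude = `boundary_irregularity` × radius) in
lesion color (120, 105, 92) on skin (232, 180, 152), blended by
`contrast_scale`, then applies, in order: a multiplicative linear
illumination gradient in a random direction (±`illumination_gradient`/2),
anti-aliased dark-brown Bezier hair strokes, radial vignetting, optional
ruler ticks, and additive Gaussian sensor noise (sd 4 by default),
clipped to 8 bits. The colors were chosen from a CIELAB analysis: the
lesion sits 31.8 below skin in L\*, 11.4 in a\* and 12.0 in b\*, so its
chroma separation is 3–4× the σ ≈ 2.9 that 8-bit sensor noise induces
in a\*/b\* — the order of chromatic SNR seen in real dermoscopic
photographs — and hair (45, 32, 26) is darker than both in every
channel, which is what makes the darker-cluster rule and the
max-filter hair removal mutually consistent. The ground-truth mask is
purely geometric and is never altered by artifact layers. Each suite
image draws its own stream from (suite seed, index), so suites are
order-independent and bit-reproducible.

What the generator does **not** emulate: dermoscopic gel and air-bubble
optics, multi-colored or multi-focal lesions, pigment networks and
other dermoscopic microstructures, JPEG artifacts, and spatially
correlated demosaicing noise. Passing the synthetic acceptance suite
therefore demonstrates the pipeline's robustness to the geometric and
photometric artifact classes modeled here, not clinical-grade accuracy
on real atlases.

## Design choices that were genuinely open

- **Third fusion channel / scalar substrate**: the mean of the two
  equalized chroma channels (the published description names three
  channels but composes only two).
- **Sub-cluster keep rule**: skin-anchored nearest-pole rule (above);
  a candidate-mean cutoff proved unstable on noisy unimodal candidates.
- **Box initialization**: the level set starts on the expanded bounding
  box of the clustering mask and shrinks (α > 0), matching the
  boundary-selection-rectangle scheme; initializing on the mask itself
  and the sign conventions are configurable through `DRLSEParams`.
- **Delaunay role**: interpreted as alpha-shape boundary
  regularization; disablable via `post.smooth=false`.
- **Class-dependent iteration budget** (600 melanoma / 1000 nevus)
  requires a diagnosis label the segmenter does not have; presets
  expose it, the default is 600 with early stopping.
- **Hausdorff normalization**: reported both raw (pixels) and divided
  by the image diagonal; the diagonal form is the scale-free default.

## Degenerate inputs

A constant (clusterless) image returns an empty mask with a warning
rather than an error; a clustering region that fills the whole frame
(no outside left for the contour) falls back to the coarse clustering
mask with a warning; an erosion that would empty the mask is skipped;
Hausdorff distance and ratio metrics with empty denominators are
reported as NaN with an `undefined` flag, never silently zero.

## Known limitations

- The fixed-width 5-px maximum filter and 5-px erosion have a
  scale-dependent footprint: at the 256×256 default working size they
  bite ≈ 2 px into a ~50-px lesion radius (≈ 0.03–0.05 Dice of
  deliberate under-segmentation, visible as a negative area bias in the
  Bland-Altman report), while at the native ~768×560 photograph scale
  the same windows are marginal. Tests of the sharp-boundary examples
  run near the native scale for this reason.
- `finalize` is intentionally not idempotent: every application
  includes the prescribed strict erosion, so repeated application keeps
  shrinking the mask. Re-running on the same input is bit-stable.
- The darker-cluster selection assumes the lesion is darker than skin
  in the equalized chroma substrate (true for pigmented melanocytic
  lesions); hypopigmented or amelanotic lesions are out of scope.
- One lesion per image: the largest dark component wins.
- Runtime is dominated by the level-set iterations (≈ 2–4 s per
  256×256 image on one CPU; quadratic in image side).
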
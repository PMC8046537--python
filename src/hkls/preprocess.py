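"""Artifact-suppressing preprocessing.

The segmentation substrate is a "fusion image" built from the chromatic
a* and b* channels of CIELAB only: lightness is discarded because
illumination gradients, vignetting and shading live mostly in L*, while
the melanin contrast between lesion and skin survives in chroma. Each
chromatic channel is histogram-equalized to stretch the (often tiny)
raw lesion/skin chroma difference to full range, the two are averaged
into a scalar substrate, thin dark structures (hair, ruler ticks) are
erased with a 5×5 gray-level maximum filter, and near-black frame or
vignette pixels are excluded by keeping the largest bright blob.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LabImage",
    "FusionImage",
    "rgb_to_lab",
    "equalize_ab",
    "build_fusion",
    "grayscale_substrate",
    "suppress_hair",
    "remove_vignette",
]


@dataclass
class LabImage:
    L: np.ndarray  # lightness, [0, 100]
    a: np.ndarray  # green–red axis
    b: np.ndarray  # blue–yellow axis


@dataclass
class FusionImage:
    """3-channel fusion substrate: (a_eq, b_eq, mean), all in [0, 1].

    ``gray`` — the scalar clustering/evolution substrate — is the
    pixelwise mean of the first two channels.
    """

    channels3: np.ndarray  # H×W×3 float
    provenance: dict = field(default_factory=dict)

    @property
    def gray(self) -> np.ndarray:
        return (self.channels3[..., 0] + self.channels3[..., 1]) / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels3.shape[:2]


def rgb_to_lab(img: np.ndarray) -> LabImage:
    """Standard sRGB → CIE L*a*b* under D65."""
    lab = color.rgb2lab(np.asarray(img, dtype=np.uint8))
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def _equalize_channel(ch: np.ndarray, bins: int = 256) -> np.ndarray:
    """Min-max rescale to [0,1], then discrete CDF histogram equalization.

    A constant channel has no histogram to equalize and is returned as
    the constant 0.5.
    """
    ch = np.asarray(ch, dtype=float)
    lo, hi = float(ch.min()), float(ch.max())
    if hi - lo < 1e-12:
        return np.full_like(ch, 0.5)
    x = (ch - lo) / (hi - lo)
    hist, _ = np.histogram(x, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist) / x.size
    idx = np.minimum((x * bins).astype(int), bins - 1)
    return cdf[idx]


def equalize_ab(lab: LabImage, bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-equalize the two chromatic channels; L is discarded."""
    return _equalize_channel(lab.a, bins), _equalize_channel(lab.b, bins)


def build_fusion(a_eq: np.ndarray, b_eq: np.ndarray, provenance: dict | None = None) -> FusionImage:
    """Stack (a_eq, b_eq, mean) into the 3-channel fusion image."""
    a_eq = np.asarray(a_eq, dtype=float)
    b_eq = np.asarray(b_eq, dtype=float)
    if a_eq.shape != b_eq.shape:
        raise ValidationError(f"channel shapes differ: {a_eq.shape} vs {b_eq.shape}")
    mean = (a_eq + b_eq) / 2.0
    channels3 = np.clip(np.stack([a_eq, b_eq, mean], axis=-1), 0.0, 1.0)
    return FusionImage(channels3=channels3, provenance=dict(provenance or {}))


def grayscale_substrate(img: np.ndarray) -> FusionImage:
    """Raw-luminance substrate (ablation baseline; no CIELAB, no equalization)."""
    gray = color.rgb2gray(np.asarray(img, dtype=np.uint8))
    lo, hi = float(gray.min()), float(gray.max())
    if hi - lo > 1e-12:
        gray = (gray - lo) / (hi - lo)
    channels3 = np.stack([gray, gray, gray], axis=-1)
    return FusionImage(channels3=channels3, provenance={"substrate": "grayscale"})


def suppress_hair(f: FusionImage, size: int = 5) -> FusionImage:
    """Erase thin dark structures with a gray-level maximum filter.

    Lesions are broad dark regions in the fusion representation while
    hair and ruler ticks are dark and thin; a ``size``×``size`` dilation
    removes anything dark narrower than ``size`` pixels, at the cost of
    eroding the lesion border by ≤ (size−1)/2 px — slack the level-set
    stage recovers.
    """
    if size <= 1:
        return f
    dilated = np.stack(
        [ndimage.grey_dilation(f.channels3[..., i], size=(size, size), mode="nearest")
         for i in range(3)],
        axis=-1,
    )
    prov = dict(f.provenance)
    prov["max_filter_size"] = size
    return FusionImage(channels3=dilated, provenance=prov)


def remove_vignette(f: FusionImage, img: np.ndarray,
                    cutoff: float = 0.15) -> tuple[FusionImage, np.ndarray]:
    """Exclude near-black frame/vignette pixels from further analysis.

    Pixels with RGB luminance below ``cutoff`` (fraction of full scale)
    are flagged dark; the valid region is the largest 8-connected blob
    of non-dark pixels. Excluded fusion pixels are replaced by the
    valid-region median so they cannot attract cluster centroids.
    """
    lum = color.rgb2gray(np.asarray(img, dtype=np.uint8))
    bright = lum >= cutoff
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(bright, structure=structure)
    if n == 0:
        logger.warning("image is entirely dark; keeping all pixels as valid")
        return f, np.ones(f.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    valid = labels == (1 + int(np.argmax(sizes)))
    if valid.sum() < 0.25 * valid.size:
        logger.warning("valid region covers only %.1f%% of the image",
                       100.0 * valid.sum() / valid.size)
    if valid.all():
        return f, valid
    channels = f.channels3.copy()
    med = np.median(channels[valid], axis=0)
    channels[~valid] = med
    prov = dict(f.provenance)
    prov["vignette_cutoff"] = cutoff
    return FusionImage(channels3=channels, provenance=prov), valid


def preprocess_image(img: np.ndarray, *, max_filter_size: int = 5,
                     vignette_cutoff: float = 0.15, equalize_bins: int = 256,
                     substrate: str = "fusion") -> tuple[FusionImage, np.ndarray]:
    """Full preprocessing chain: substrate → hair suppression → vignette removal."""
    if substrate == "grayscale":
        f = grayscale_substrate(img)
    else:
        lab = rgb_to_lab(img)
        a_eq, b_eq = equalize_ab(lab, bins=equalize_bins)
        f = build_fusion(a_eq, b_eq, provenance={"substrate": "fusion",
                                                 "equalize_bins": equalize_bins})
    f = suppress_hair(f, size=max_filter_size)
    return remove_vignette(f, img, cutoff=vignette_cutoff)
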
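"""Morphological cleanup of the level-set mask into the final border.

Order follows the method's narrative: fill the border interior, erode
with a 5-px square, regularize the boundary with a Delaunay/alpha-shape
step, and fill once more to guard against triangulation slivers. The
result is a single connected lesion component (or empty).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.draw import polygon

logger = logging.getLogger(__name__)

__all__ = ["fill_border_interior", "erode_mask", "smooth_boundary",
           "largest_component", "finalize"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def fill_border_interior(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed holes (flood-fill from the image border on the complement)."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def erode_mask(mask: np.ndarray, width_px: int = 5) -> np.ndarray:
    """Binary erosion with a square element; borders count as background.

    If erosion would empty the mask the input is returned unchanged.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be odd and >= 1")
    mask = np.asarray(mask, dtype=bool)
    if width_px == 1:
        return mask.copy()
    eroded = ndimage.binary_erosion(mask, structure=np.ones((width_px, width_px),
                                                            dtype=bool),
                                    border_value=0)
    if mask.any() and not eroded.any():
        logger.warning("erosion with a %d-px square would empty the mask; "
                       "returning it unchanged", width_px)
        return mask.copy()
    return eroded


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return np.argwhere(mask & ~inner)


def smooth_boundary(mask: np.ndarray, lmax: float = 30.0) -> np.ndarray:
    """Alpha-shape-style boundary regularization via Delaunay triangulation.

    Triangulates the boundary pixels, keeps triangles whose longest edge
    is at most ``lmax``, and unions their rasterization with the input
    (bridging cracks and smoothing jagged borders); the largest
    8-connected component is returned.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = _boundary_points(mask)
    if len(pts) < 3:
        return mask.copy()
    try:
        tri = Delaunay(pts)
    except QhullError:  # collinear boundary
        return mask.copy()
    out = mask.copy()
    simplices = tri.simplices
    verts = pts[simplices]  # (n_tri, 3, 2)
    edges = verts - np.roll(verts, 1, axis=1)
    max_edge = np.sqrt((edges ** 2).sum(axis=2)).max(axis=1)
    for v in verts[max_edge <= lmax]:
        rr, cc = polygon(v[:, 0], v[:, 1], shape=mask.shape)
        out[rr, cc] = True
    return largest_component(out)


def largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT8)
    if n <= 1:
        return np.asarray(mask, dtype=bool).copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def finalize(mask: np.ndarray, erode_width: int = 5, smooth: bool = True,
             lmax: float = 30.0) -> np.ndarray:
    """fill → erode → smooth → fill, restricted to the largest component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        logger.warning("finalize called on an empty mask")
        return mask.copy()
    out = largest_component(fill_border_interior(mask))
    out = erode_mask(out, erode_width)
    if smooth:
        out = smooth_boundary(out, lmax=lmax)
    out = largest_component(fill_border_interior(out))
    return out
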
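"""Hierarchical (two-level, top-down) K-means initial-contour estimation.

Level 1 splits the valid fusion-gray pixels into K1 clusters (default 2:
lesion-like dark vs skin-like bright). The darker cluster — the lesion
candidate — is re-clustered into K2 sub-clusters (default 3) and the
darkest sub-clusters are kept, yielding a coarse lesion region whose
bounding box seeds the level-set refinement. Lloyd's algorithm with
squared-Euclidean assignment, k-means++ seeding and a fixed iteration
budget (default 20 per level) is implemented here because the cluster
bookkeeping (empty-cluster reseeding, per-iteration SSE monotonicity,
candidate-only splitting) is part of the method itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import ValidationError
from .preprocess import FusionImage

logger = logging.getLogger(__name__)

__all__ = ["HKParams", "ClusterLabels", "InitialRegion", "kmeans",
           "hk_segment", "select_initial_region"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HKParams:
    k1: int = 2
    k2: int = 3
    max_iter: int = 20
    n_restarts: int = 1
    seed: int = 0
    split_all: bool = False

    def __post_init__(self):
        if self.k1 < 2 or self.k2 < 2:
            raise ValidationError("K1 and K2 must both be >= 2")


@dataclass
class ClusterLabels:
    """Final label field: -1 outside the valid region, small ints inside."""

    labels: np.ndarray  # H×W int
    level: int
    centroids: dict[int, float]  # label id -> mean fusion gray
    lesion_sublabels: tuple[int, ...] = ()  # level-2 ids inside the candidate
    candidate_mean: float = float("nan")  # mean gray of the level-1 candidate
    background_mean: float = float("nan")  # mean gray outside the candidate
    degenerate: bool = False


@dataclass
class InitialRegion:
    mask: np.ndarray  # BinaryMask, largest dark component, holes filled
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area_fraction: float


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding (squared-Euclidean weighting)."""
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]), dtype=float)
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j:] = centroids[0]
            break
        probs = d2 / total
        centroids[j] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(axis=1))
    return centroids


def kmeans(features: np.ndarray, k: int, max_iter: int = 20, seed: int = 0,
           n_restarts: int = 1) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's K-means with squared-Euclidean distance.

    Returns (assignments, centroids, sse). Stops at ``max_iter`` or when
    assignments no longer change; an emptied cluster is re-seeded to the
    point farthest from its current centroid. The per-iteration SSE is
    checked to be non-increasing.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k > n:
        raise ValidationError(f"K={k} exceeds number of points n={n}")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        centroids = _kmeans_pp_init(x, k, rng)
        assign = np.full(n, -1, dtype=int)
        prev_sse = np.inf
        for _it in range(max_iter):
            d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new_assign = np.argmin(d2, axis=1)
            sse = float(d2[np.arange(n), new_assign].sum())
            assert sse <= prev_sse * (1 + 1e-9) + 1e-12, "SSE increased"
            prev_sse = sse
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                members = x[assign == j]
                if len(members):
                    centroids[j] = members.mean(axis=0)
                else:
                    far = int(np.argmax(d2[np.arange(n), assign]))
                    if d2[far, assign[far]] > 0:
                        centroids[j] = x[far]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        sse = float(d2[np.arange(n), assign].sum())
        if best is None or sse < best[2]:
            best = (assign, centroids.copy(), sse)
    return best


def hk_segment(f: FusionImage, valid_region: np.ndarray | None = None,
               params: HKParams | None = None) -> ClusterLabels:
    """Two-level top-down K-means on the scalar fusion substrate.

    Level 1 uses K1 clusters; the darkest-centroid cluster (the lesion
    candidate) is re-clustered with K2. Final labels are the K2
    sub-cluster ids inside the candidate plus one background id per
    remaining level-1 cluster (or all level-1 clusters split when
    ``split_all``).
    """
    p = params or HKParams()
    gray = f.gray
    valid = (np.ones(gray.shape, dtype=bool) if valid_region is None
             else np.asarray(valid_region, dtype=bool))
    vals = gray[valid]
    if vals.size < p.k1 * p.k2:
        raise ValidationError("valid region too small for the requested clusters")

    labels = np.full(gray.shape, -1, dtype=int)
    if float(vals.max() - vals.min()) < 1e-9:
        logger.warning("constant fusion image: single-cluster labels")
        labels[valid] = 0
        return ClusterLabels(labels=labels, level=1,
                             centroids={0: float(vals.mean())},
                             degenerate=True)

    assign1, cent1, _ = kmeans(vals, p.k1, max_iter=p.max_iter, seed=p.seed,
                               n_restarts=p.n_restarts)
    cent1 = cent1[:, 0]
    candidate = int(np.argmin(cent1))

    split_ids = range(p.k1) if p.split_all else (candidate,)
    centroids: dict[int, float] = {}
    lesion_sublabels: list[int] = []
    next_id = 0
    for c in range(p.k1):
        sel = assign1 == c
        if c in split_ids and sel.sum() >= p.k2:
            sub_assign, sub_cent, _ = kmeans(vals[sel], p.k2, max_iter=p.max_iter,
                                             seed=p.seed + 1 + c,
                                             n_restarts=p.n_restarts)
            ids = []
            for j in range(p.k2):
                members = sub_assign == j
                if not members.any():
                    continue
                centroids[next_id] = float(vals[sel][members].mean())
                ids.append(next_id)
                next_id += 1
            remap = {}
            kept = [j for j in range(p.k2) if (sub_assign == j).any()]
            for new_id, j in zip(ids, kept):
                remap[j] = new_id
            lab_sel = np.array([remap[j] for j in sub_assign])
            tmp = labels[valid]
            tmp[sel] = lab_sel
            labels[valid] = tmp
            if c == candidate:
                lesion_sublabels = ids
        else:
            centroids[next_id] = float(vals[sel].mean())
            tmp = labels[valid]
            tmp[sel] = next_id
            labels[valid] = tmp
            if c == candidate:
                lesion_sublabels = [next_id]
            next_id += 1

    return ClusterLabels(labels=labels, level=2, centroids=centroids,
                         lesion_sublabels=tuple(lesion_sublabels),
                         candidate_mean=float(vals[assign1 == candidate].mean()),
                         background_mean=float(vals[assign1 != candidate].mean()))


def _component_key(gray, comp_mask):
    """Sort key: larger first, then darker mean gray, then top-left bbox."""
    rows, cols = np.nonzero(comp_mask)
    return (-comp_mask.sum(), float(gray[comp_mask].mean()),
            int(rows.min()), int(cols.min()))


def select_initial_region(labels: ClusterLabels, f: FusionImage) -> InitialRegion:
    """Distil the cluster labels into the initial lesion region R0.

    Keeps the lesion-like (darkest) level-2 sub-clusters of the lesion
    candidate, then takes the largest 8-connected component and fills
    its holes. A sub-cluster counts as lesion-like when its centroid is
    closer to the candidate's dark pole (the darkest sub-centroid) than
    to the background (skin) gray — anchoring the cutoff to the skin
    level keeps the rule stable when the candidate is a single noisy
    mode whose sub-centroids are evenly spaced, while still rejecting
    bright fringe or shadow sub-clusters that sit nearer the skin tone.
    Ties on component size break toward the darker, then top-left-most
    component.
    """
    gray = f.gray
    if labels.degenerate:
        raise ValidationError("degenerate single-cluster labels: no lesion candidate")
    cents = [labels.centroids[i] for i in labels.lesion_sublabels]
    cutoff = (min(cents) + labels.background_mean) / 2.0
    kept = [i for i in labels.lesion_sublabels
            if labels.centroids[i] <= cutoff + 1e-12]
    if not kept:
        logger.warning("no sub-cluster at or below candidate mean; "
                       "falling back to the whole candidate cluster")
        kept = list(labels.lesion_sublabels)
    sel = np.isin(labels.labels, kept)
    if not sel.any():
        raise ValidationError("empty lesion candidate region")

    comp, n = ndimage.label(sel, structure=_STRUCT8)
    best = min((_component_key(gray, comp == i), i) for i in range(1, n + 1))[1]
    mask = ndimage.binary_fill_holes(comp == best)

    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    return InitialRegion(mask=mask, bbox=bbox,
                         area_fraction=float(mask.sum()) / mask.size)
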
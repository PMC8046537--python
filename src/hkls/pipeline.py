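"""End-to-end orchestration: preprocess → HK clustering → DRLSE → postprocess.

``segment`` runs the full chain on one RGB image and is deterministic
given (image bytes, config). ``sweep_clusters`` reruns it across
(K1, K2) combinations on a synthetic suite, reproducing the
cluster-count selection experiment structurally (accuracy/runtime per
combination) on data we control.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import drlse as _drlse
from . import postprocess as _post
from .config import PipelineConfig
from .evaluate import evaluate_pair
from .hk_cluster import hk_segment, select_initial_region
from .io_formats import ResultRecord, ValidationError
from .preprocess import preprocess_image

logger = logging.getLogger(__name__)

__all__ = ["segment", "sweep_clusters"]


def _dump_debug(debug_dir, image_id, **arrays):
    """Write stage intermediates as grayscale PNGs for visual inspection."""
    from pathlib import Path

    from .io_formats import write_mask
    from PIL import Image

    out = Path(debug_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in arrays.items():
        path = out / f"{image_id}_{name}.png"
        if arr.dtype == bool:
            write_mask(arr, path)
        else:
            lo, hi = float(arr.min()), float(arr.max())
            scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
            Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)


def segment(img: np.ndarray, cfg: PipelineConfig | None = None,
            truth: np.ndarray | None = None,
            image_id: str = "image",
            debug_dir=None) -> tuple[np.ndarray, ResultRecord]:
    """Segment one lesion image; returns (mask, record).

    A degenerate image (no clusterable contrast) yields an empty mask
    and a warning in the record rather than an exception. With
    ``debug_dir`` set, stage intermediates (fusion substrate, cluster
    labels, initial region, final φ) are written as PNG panels.
    """
    cfg = cfg or PipelineConfig()
    rec = ResultRecord(image_id=image_id, parameters=cfg.to_dict())
    t0 = time.perf_counter()
    stage = "preprocess"
    try:
        f, valid = preprocess_image(
            img,
            max_filter_size=cfg.preprocess.max_filter_size,
            vignette_cutoff=cfg.preprocess.vignette_cutoff,
            equalize_bins=cfg.preprocess.equalize_bins,
            substrate=cfg.preprocess.substrate,
        )
        stage = "hk_cluster"
        labels = hk_segment(f, valid, cfg.hk)
        if labels.degenerate:
            rec.warnings.append("degenerate fusion image; returning empty mask")
            rec.runtime_seconds = time.perf_counter() - t0
            return np.zeros(img.shape[:2], dtype=bool), rec
        region = select_initial_region(labels, f)

        stage = "drlse"
        phi = g = None
        try:
            g = _drlse.edge_indicator(f, sigma=cfg.drlse.sigma)
            phi0 = _drlse.init_lsf(region, img.shape[:2], c0=cfg.drlse.c0,
                                   margin_px=cfg.drlse.margin_px)
            alpha = _drlse.choose_alpha(region, cfg.drlse)
            phi = _drlse.evolve(phi0, g, cfg.drlse, alpha=alpha)
            mask = _drlse.extract_mask(phi, threshold_8bit=cfg.drlse.mask_threshold,
                                       c0=cfg.drlse.c0)
        except ValidationError as exc:
            # e.g. the clustering region fills the frame and leaves no
            # outside for the contour: fall back to the coarse HK mask
            logger.warning("level set could not run (%s); "
                           "falling back to the clustering mask", exc)
            rec.warnings.append(f"drlse fallback to HK mask: {exc}")
            mask = region.mask
        if debug_dir is not None:
            panels = {"fusion": f.gray, "valid": valid,
                      "labels": labels.labels.astype(float),
                      "initial_region": region.mask}
            if g is not None:
                panels["edge_indicator"] = g.g
            if phi is not None:
                panels["phi"] = phi.phi
            _dump_debug(debug_dir, image_id, **panels)

        stage = "postprocess"
        mask = mask & valid
        mask = _post.finalize(mask, erode_width=cfg.post.erode_width,
                              smooth=cfg.post.smooth, lmax=cfg.post.lmax)
    except (ValidationError, FloatingPointError) as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    rec.runtime_seconds = time.perf_counter() - t0
    if truth is not None:
        valid_eval = valid if not valid.all() else None
        rec.metrics = evaluate_pair(mask, truth, valid_eval)
    return mask, rec


def sweep_clusters(suite, k1_values, k2_values,
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Segment every suite image for each (K1, K2); one summary row each."""
    if not suite:
        raise ValidationError("sweep requires a non-empty suite")
    cfg = cfg or PipelineConfig()
    rows = []
    for k1 in k1_values:
        for k2 in k2_values:
            c = cfg.with_overrides({"hk.k1": int(k1), "hk.k2": int(k2)})
            accs, dices, times = [], [], []
            for i, (img, truth, _spec) in enumerate(suite):
                mask, rec = segment(img, c, truth=truth, image_id=f"img_{i:03d}")
                accs.append(rec.metrics.accuracy)
                dices.append(rec.metrics.dice)
                times.append(rec.runtime_seconds)
            rows.append({"k1": int(k1), "k2": int(k2),
                         "mean_accuracy": float(np.mean(accs)),
                         "mean_dice": float(np.mean(dices)),
                         "mean_runtime_s": float(np.mean(times)),
                         "n_images": len(suite)})
    return pd.DataFrame(rows)
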
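"""Segmentation agreement statistics.

Confusion-based measures (accuracy, sensitivity, specificity, Jaccard,
Dice, F-measure), symmetric Hausdorff distance between boundary pixel
sets, and study-level Bland-Altman / linear-regression agreement of
lesion areas. Ratios with a zero denominator are reported as NaN and
flagged, never silently zeroed.

The Hausdorff distance is reported both in raw pixels and normalized
by the image diagonal, the latter being the scale on which values are
comparable across image sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import directed_hausdorff

from .io_formats import ValidationError

__all__ = ["ConfusionCounts", "SegMetrics", "AgreementReport", "confusion",
           "metrics", "hausdorff", "boundary_points", "agreement",
           "evaluate_pair", "bland_altman_plot", "regression_plot"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SegMetrics:
    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    jaccard: float = math.nan
    dice: float = math.nan
    f_measure: float = math.nan
    hausdorff_px: float = math.nan
    hausdorff_norm: float = math.nan
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("accuracy", "sensitivity", "specificity", "jaccard", "dice",
                 "f_measure", "hausdorff_px", "hausdorff_norm")}


@dataclass
class AgreementReport:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r: float
    undefined: frozenset[str] = field(default_factory=frozenset)


def confusion(pred: np.ndarray, truth: np.ndarray,
              valid: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts, restricted to ``valid`` when given."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != pred.shape:
            raise ValidationError(f"valid-region shape {valid.shape} differs "
                                  f"from mask shape {pred.shape}")
        pred, truth = pred[valid], truth[valid]
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def metrics(c: ConfusionCounts) -> SegMetrics:
    """Confusion-derived measures; zero denominators flagged as undefined."""
    if c.total == 0:
        raise ValidationError("confusion counts are all zero")
    undefined: set[str] = set()

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    m = SegMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=ratio("sensitivity", c.tp, c.tp + c.fn),
        specificity=ratio("specificity", c.tn, c.tn + c.fp),
        jaccard=ratio("jaccard", c.tp, c.tp + c.fp + c.fn),
        dice=ratio("dice", 2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )
    precision = ratio("f_measure", c.tp, c.tp + c.fp)
    recall = m.sensitivity
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        undefined.add("f_measure")
        m.f_measure = math.nan
    else:
        m.f_measure = 2 * precision * recall / (precision + recall)
    m.undefined = frozenset(undefined)
    return m


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """8-connected boundary pixels (mask pixels with a background 8-neighbor)."""
    mask = np.asarray(mask, dtype=bool)
    inner = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return np.argwhere(mask & ~inner)


def hausdorff(pred: np.ndarray, truth: np.ndarray,
              normalized: bool = True) -> float:
    """Symmetric Hausdorff distance between boundary pixel sets.

    In Euclidean pixels, divided by the image diagonal when
    ``normalized`` (the scale-free form reported by default).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError("shape mismatch between masks")
    if not pred.any() or not truth.any():
        raise ValidationError("Hausdorff distance requires two non-empty masks")
    bp, bt = boundary_points(pred).astype(float), boundary_points(truth).astype(float)
    d = max(directed_hausdorff(bp, bt)[0], directed_hausdorff(bt, bp)[0])
    if not normalized:
        return float(d)
    diag = math.hypot(*pred.shape)
    return float(d / diag)


def evaluate_pair(pred: np.ndarray, truth: np.ndarray,
                  valid: np.ndarray | None = None) -> SegMetrics:
    """All per-image metrics for one (prediction, ground truth) pair."""
    m = metrics(confusion(pred, truth, valid))
    if pred.any() and truth.any():
        m.hausdorff_px = hausdorff(pred, truth, normalized=False)
        m.hausdorff_norm = hausdorff(pred, truth, normalized=True)
    else:
        m.undefined = m.undefined | {"hausdorff_px", "hausdorff_norm"}
    return m


def agreement(areas_pred, areas_truth) -> AgreementReport:
    """Bland-Altman bias/limits plus OLS regression of predicted on true areas."""
    pred = np.asarray(areas_pred, dtype=float)
    truth = np.asarray(areas_truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValidationError("area lists must be 1-D and of equal length")
    if len(pred) < 3:
        raise ValidationError("agreement analysis needs at least 3 image pairs")
    diff = pred - truth
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    undefined: set[str] = set()
    if truth.std() == 0:
        slope = intercept = r = math.nan
        undefined |= {"slope", "intercept", "r"}
    else:
        res = stats.linregress(truth, pred)
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    return AgreementReport(mean_diff=mean_diff, sd_diff=sd_diff,
                           loa_low=mean_diff - 1.96 * sd_diff,
                           loa_high=mean_diff + 1.96 * sd_diff,
                           slope=slope, intercept=intercept, r=r,
                           undefined=frozenset(undefined))


def bland_altman_plot(areas_pred, areas_truth, path):
    """Scatter of area differences against means with bias and 1.96·SD limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = agreement(areas_pred, areas_truth)
    pred = np.asarray(areas_pred, dtype=float)
    truth = np.asarray(areas_truth, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((pred + truth) / 2, pred - truth, s=14, alpha=0.7)
    for y, style in ((rep.mean_diff, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean lesion area (px²)")
    ax.set_ylabel("area difference, predicted − truth (px²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep


def regression_plot(areas_pred, areas_truth, path):
    """Predicted-vs-true lesion area scatter with the OLS fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = agreement(areas_pred, areas_truth)
    pred = np.asarray(areas_pred, dtype=float)
    truth = np.asarray(areas_truth, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(truth, pred, s=14, alpha=0.7)
    if not math.isnan(rep.slope):
        xs = np.linspace(truth.min(), truth.max(), 50)
        ax.plot(xs, rep.slope * xs + rep.intercept, "k-", linewidth=0.8,
                label=f"y = {rep.slope:.3f}x + {rep.intercept:.0f} (r={rep.r:.3f})")
        ax.legend(fontsize=8)
    ax.set_xlabel("true lesion area (px²)")
    ax.set_ylabel("predicted lesion area (px²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep
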
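"""Image and mask I/O plus per-image result serialization.

Conventions used package-wide: arrays are row-major, 0-based, indexed
(row, col); images are H×W×3 uint8; masks are H×W bool serialized as
single-channel 0/255 PNG. Mask binarization threshold is 127 so both
0/1 and 0/255 encodings parse correctly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from PIL import Image

MIN_SIDE = 32

__all__ = [
    "MIN_SIDE",
    "ResultRecord",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_results",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ResultRecord:
    """Per-image segmentation outcome with enough context to re-run."""

    image_id: str
    predicted_mask_path: str = ""
    metrics: Any = None
    parameters: dict = field(default_factory=dict)
    runtime_seconds: float = 0.0
    warnings: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.parameters, sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit color image as an H×W×3 uint8 array.

    Grayscale inputs are replicated to 3 channels; alpha is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot decode image file {path!s}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"unexpected image layout {arr.shape} for {path!s}")
    h, w = arr.shape[:2]
    if h < MIN_SIDE or w < MIN_SIDE:
        raise ValidationError(
            f"image {path!s} is {h}×{w}; minimum supported size is "
            f"{MIN_SIDE}×{MIN_SIDE}"
        )
    return arr


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary lesion mask (true = lesion).

    Pixels > 127 map to true. Color masks are reduced with any-channel
    > 127. If ``expected_shape`` is given a mismatch raises.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot decode mask file {path!s}: {exc}") from exc
    if arr.ndim == 3:
        mask = (arr[..., :3] > 127).any(axis=2)
    else:
        mask = arr > 127
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValidationError(
            f"mask {path!s} has shape {mask.shape}, expected {tuple(expected_shape)}"
        )
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an H×W×3 uint8 image as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def write_results(records: Sequence[ResultRecord], csv_path: str | Path,
                  json_path: str | Path | None = None) -> pd.DataFrame:
    """Serialize results as one CSV row per image plus a JSON config sidecar."""
    rows = []
    for rec in records:
        row: dict[str, Any] = {"image_id": rec.image_id}
        if rec.metrics is not None:
            row.update(rec.metrics.as_dict())
        row["runtime_seconds"] = rec.runtime_seconds
        row["config_hash"] = rec.config_hash
        rows.append(row)
    df = pd.DataFrame(rows)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            rec.image_id: {
                "parameters": rec.parameters,
                "predicted_mask_path": rec.predicted_mask_path,
                "warnings": rec.warnings,
            }
            for rec in records
        }
        Path(json_path).write_text(json.dumps(sidecar, indent=2, default=str))
    return df
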
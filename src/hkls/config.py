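"""Flat-key pipeline configuration.

Every default equals the method's stated parameter where one exists
(K1=2, K2=3, 20 k-means iterations; μ=0.02, λ=5, ε=1.5, c0=3, dt=8,
σ=1.5, α∈{3,5}, 600/1000 iterations; binarization threshold 80; 5-px
erosion). Keys use the ``stage.name`` form (e.g. ``hk.k1``,
``drlse.mu``); a TOML file may supply them as tables, and CLI flags
override file values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .hk_cluster import HKParams
from .drlse import DRLSEParams

__all__ = ["PreprocessConfig", "PostprocessConfig", "PipelineConfig"]


@dataclass(frozen=True)
class PreprocessConfig:
    max_filter_size: int = 5
    vignette_cutoff: float = 0.15
    equalize_bins: int = 256
    substrate: str = "fusion"  # "fusion" or "grayscale" (ablation)


@dataclass(frozen=True)
class PostprocessConfig:
    erode_width: int = 5
    smooth: bool = True
    lmax: float = 30.0


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hk: HKParams = field(default_factory=HKParams)
    drlse: DRLSEParams = field(default_factory=DRLSEParams)
    post: PostprocessConfig = field(default_factory=PostprocessConfig)

    _SECTION_TYPES = {
        "preprocess": PreprocessConfig,
        "hk": HKParams,
        "drlse": DRLSEParams,
        "post": PostprocessConfig,
    }
    _ALIASES = {"drlse.lambda": "drlse.lam"}

    def to_dict(self) -> dict[str, Any]:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in self._SECTION_TYPES}

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    def with_overrides(self, overrides: dict[str, Any]) -> "PipelineConfig":
        """Apply flat ``stage.key`` → value overrides."""
        staged: dict[str, dict[str, Any]] = {}
        for key, value in overrides.items():
            key = self._ALIASES.get(key, key)
            stage, _, name = key.partition(".")
            if stage not in self._SECTION_TYPES or not name:
                raise KeyError(f"unknown config key {key!r}")
            valid = {f.name for f in dataclasses.fields(self._SECTION_TYPES[stage])}
            if name not in valid:
                raise KeyError(f"unknown config key {key!r}")
            staged.setdefault(stage, {})[name] = value
        replaced = {
            stage: dataclasses.replace(getattr(self, stage), **kwargs)
            for stage, kwargs in staged.items()
        }
        return dataclasses.replace(self, **replaced)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        flat = {}
        for stage, table in data.items():
            if not isinstance(table, dict):
                raise KeyError(f"top-level key {stage!r} is not a config section")
            for name, value in table.items():
                flat[f"{stage}.{name}"] = value
        return cls().with_overrides(flat)

    def preset(self, name: str) -> "PipelineConfig":
        """Lesion-class presets: iteration budget 600 (melanoma) / 1000 (nevus)."""
        if name == "melanoma":
            return self.with_overrides({"drlse.n_iter": 600})
        if name == "nevus":
            return self.with_overrides({"drlse.n_iter": 1000})
        raise KeyError(f"unknown preset {name!r}; expected 'melanoma' or 'nevus'")
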
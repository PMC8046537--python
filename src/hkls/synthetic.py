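"""Seeded synthetic dermoscopic-style images with ground-truth masks.

Emulates the artifact classes that plague lesion photographs — hair
strokes, corner vignetting, ruler markings, smooth illumination
gradients, sensor noise — over a darker, reddish-brown elliptical
lesion on lighter skin. The ground-truth mask is purely geometric
(the perturbed ellipse) and is never altered by artifact layers, so
pipeline accuracy can be scored without any external dataset.

Default colors were chosen from a CIELAB analysis: the lesion color
(120,105,92) — L*=45.5, a*=3.7, b*=9.5 — sits below the skin color
(232,180,152) — L*=77.3, a*=15.1, b*=21.5 — in all three axes, giving
the darker, lower-chroma brown of a melanocytic lesion on light skin
with a chroma separation of 11–12 Lab units, the order of magnitude
seen between pigmented lesions and surrounding skin in dermoscopic
photographs (sensor noise of a few 8-bit units maps to σ ≈ 2–3 Lab
units, so the chromatic SNR is a realistic 3–4 per channel). Hair
(45,32,26) is darker than both in every channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_formats import ValidationError, write_image, write_mask

__all__ = ["SyntheticSpec", "generate_image", "generate_suite", "write_suite"]

_MARGIN_PX = 5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic lesion image."""

    seed: int = 0
    image_size: tuple[int, int] = (256, 256)
    lesion_center: tuple[float, float] = (0.5, 0.5)  # fractions of (H, W)
    lesion_radii: tuple[float, float] = (60.0, 45.0)  # pixels (r_row, r_col)
    boundary_irregularity: float = 0.15
    lesion_color_rgb: tuple[int, int, int] = (120, 105, 92)
    skin_color_rgb: tuple[int, int, int] = (232, 180, 152)
    contrast_scale: float = 0.85
    n_hairs: int = 8
    hair_thickness_px: int = 2
    hair_color_rgb: tuple[int, int, int] = (45, 32, 26)
    vignette_strength: float = 0.3
    illumination_gradient: float = 0.25
    ruler_marks: bool = False
    noise_sd: float = 4.0
    edge_softness_px: float = 1.0

    def validate(self) -> None:
        h, w = self.image_size
        cr, cc = self.lesion_center[0] * h, self.lesion_center[1] * w
        rmax = (1.0 + self.boundary_irregularity)
        rr, rc = self.lesion_radii[0] * rmax, self.lesion_radii[1] * rmax
        if (cr - rr < _MARGIN_PX or cr + rr > h - _MARGIN_PX
                or cc - rc < _MARGIN_PX or cc + rc > w - _MARGIN_PX):
            raise ValidationError(
                f"lesion (center=({cr:.0f},{cc:.0f}), radii=({rr:.0f},{rc:.0f})) "
                f"does not fit in {h}×{w} with a {_MARGIN_PX}-px margin"
            )
        if not (0.0 < self.contrast_scale <= 1.0):
            raise ValidationError("contrast_scale must lie in (0, 1]")
        if self.boundary_irregularity < 0 or self.noise_sd < 0:
            raise ValidationError("irregularity and noise_sd must be >= 0")
        if not (0.0 <= self.vignette_strength <= 1.0
                and 0.0 <= self.illumination_gradient <= 1.0):
            raise ValidationError("vignette/illumination strengths must lie in [0, 1]")


def _boundary_perturbation(rng: np.random.Generator, n_harmonics: int = 4):
    """Smooth 2π-periodic perturbation with max |p| <= 1."""
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0.3, 1.0, n_harmonics) / ks
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)

    def p(theta: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta)
        for k, a, ph in zip(ks, amps, phases):
            out += a * np.cos(k * theta + ph)
        peak = np.abs(out).max()
        return out / peak if peak > 0 else out

    return p


def _lesion_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    cr, cc = spec.lesion_center[0] * h, spec.lesion_center[1] * w
    rows, cols = np.mgrid[0:h, 0:w]
    u = (rows - cr) / spec.lesion_radii[0]
    v = (cols - cc) / spec.lesion_radii[1]
    rho = np.hypot(u, v)
    if spec.boundary_irregularity == 0:
        return rho <= 1.0
    theta = np.arctan2(u, v)
    p = _boundary_perturbation(rng)
    return rho <= 1.0 + spec.boundary_irregularity * p(theta)


def _draw_hairs(shape, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Opacity canvas in [0,1]: anti-aliased dark polyline strokes."""
    h, w = shape
    canvas = np.zeros(shape, dtype=float)
    for _ in range(spec.n_hairs):
        # quadratic Bezier spanning a good part of the frame
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p2 = rng.uniform([0, 0], [h - 1, w - 1])
        mid = (p0 + p2) / 2
        p1 = mid + rng.uniform(-0.4, 0.4, 2) * np.array([h, w])
        t = np.linspace(0, 1, 4 * max(h, w))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        stroke = np.zeros(shape, dtype=float)
        stroke[rr, cc] = 1.0
        if spec.hair_thickness_px > 1:
            k = spec.hair_thickness_px
            stroke = ndimage.grey_dilation(stroke, size=(k, k))
        # soften edges so hair is anti-aliased, forcing real work from
        # the 5×5 maximum filter downstream
        stroke = ndimage.gaussian_filter(stroke, 0.6)
        canvas = np.maximum(canvas, np.clip(stroke, 0, 1))
    return canvas


def _ruler_ticks(shape) -> np.ndarray:
    """Opacity canvas of dark ruler tick marks along the bottom edge."""
    h, w = shape
    canvas = np.zeros(shape, dtype=float)
    row0 = h - 18
    for i, c in enumerate(range(10, w - 10, 12)):
        length = 12 if i % 5 == 0 else 7
        canvas[row0:row0 + length, c:c + 2] = 1.0
    return canvas


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one (RgbImage, BinaryMask) pair; identical spec ⇒ identical output.

    Layer order: skin/lesion blend, multiplicative illumination gradient,
    hair strokes, vignette, optional ruler ticks, additive Gaussian noise,
    clip to [0, 255].
    """
    spec.validate()
    h, w = spec.image_size
    # independent child streams so the mask never depends on artifact params
    ss = np.random.SeedSequence(spec.seed)
    rng_shape, rng_hair, rng_noise, rng_illum = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    mask = _lesion_mask(spec, rng_shape)

    skin = np.asarray(spec.skin_color_rgb, dtype=float)
    lesion = skin + spec.contrast_scale * (
        np.asarray(spec.lesion_color_rgb, dtype=float) - skin
    )
    blend = mask.astype(float)
    if spec.edge_softness_px > 0:
        blend = ndimage.gaussian_filter(blend, spec.edge_softness_px)
    img = skin[None, None, :] + blend[..., None] * (lesion - skin)[None, None, :]

    if spec.illumination_gradient > 0:
        angle = rng_illum.uniform(0, 2 * np.pi)
        rows, cols = np.mgrid[0:h, 0:w]
        t = (np.cos(angle) * rows / max(h - 1, 1)
             + np.sin(angle) * cols / max(w - 1, 1))
        t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
        gain = 1.0 + spec.illumination_gradient * (t - 0.5)
        img *= gain[..., None]

    if spec.n_hairs > 0:
        opacity = _draw_hairs((h, w), spec, rng_hair)
        hair = np.asarray(spec.hair_color_rgb, dtype=float)
        img = img * (1 - opacity[..., None]) + hair[None, None, :] * opacity[..., None]

    if spec.vignette_strength > 0:
        rows, cols = np.mgrid[0:h, 0:w]
        r2 = (((rows - (h - 1) / 2) / ((h - 1) / 2)) ** 2
              + ((cols - (w - 1) / 2) / ((w - 1) / 2)) ** 2) / 2.0
        img *= (1.0 - spec.vignette_strength * r2)[..., None]

    if spec.ruler_marks:
        opacity = _ruler_ticks((h, w))
        tick = np.array([40.0, 40.0, 45.0])
        img = img * (1 - opacity[..., None]) + tick[None, None, :] * opacity[..., None]

    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, img.shape)

    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_suite(n: int, base_spec: SyntheticSpec | None = None,
                   seed: int = 7) -> list[tuple[np.ndarray, np.ndarray, SyntheticSpec]]:
    """Generate ``n`` jittered variants of ``base_spec``.

    Each image gets its own pseudo-random stream derived from
    (suite seed, index), so the suite is order-independent and
    re-running with the same seed reproduces it bit for bit.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    base = base_spec if base_spec is not None else SyntheticSpec()
    out = []
    for i in range(n):
        child = np.random.SeedSequence([seed, i])
        rng = np.random.default_rng(child)
        image_seed = int(rng.integers(0, 2 ** 31 - 1))
        if i == 0:
            spec = replace(base, seed=image_seed)
        else:
            h, w = base.image_size
            scale = rng.uniform(0.7, 1.3)
            spec = replace(
                base,
                seed=image_seed,
                lesion_center=(
                    float(np.clip(base.lesion_center[0] + rng.uniform(-0.06, 0.06),
                                  0.3, 0.7)),
                    float(np.clip(base.lesion_center[1] + rng.uniform(-0.06, 0.06),
                                  0.3, 0.7)),
                ),
                lesion_radii=(base.lesion_radii[0] * scale,
                              base.lesion_radii[1] * scale * rng.uniform(0.85, 1.15)),
                boundary_irregularity=float(
                    np.clip(base.boundary_irregularity * rng.uniform(0.5, 1.5), 0, 0.3)),
                contrast_scale=float(
                    np.clip(base.contrast_scale * rng.uniform(0.8, 1.1), 0.4, 1.0)),
                n_hairs=int(rng.integers(0, 2 * max(base.n_hairs, 1) + 1)),
                vignette_strength=float(
                    np.clip(base.vignette_strength * rng.uniform(0.5, 1.5), 0, 0.6)),
                illumination_gradient=float(
                    np.clip(base.illumination_gradient * rng.uniform(0.5, 1.5), 0, 0.5)),
                ruler_marks=bool(rng.random() < 0.3),
            )
        img, mask = generate_image(spec)
        out.append((img, mask, spec))
    return out


def write_suite(suite, out_dir: str | Path) -> None:
    """Write ``img_###.png`` + ``mask_###.png`` + ``specs.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = {}
    for i, (img, mask, spec) in enumerate(suite):
        write_image(img, out_dir / f"img_{i:03d}.png")
        write_mask(mask, out_dir / f"mask_{i:03d}.png")
        specs[f"img_{i:03d}"] = asdict(spec)
    (out_dir / "specs.json").write_text(json.dumps(specs, indent=2))
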
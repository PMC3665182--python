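"""Synthetic test images with exact ground-truth masks.

Three fixtures exercise the properties segmentation methods are judged on:

* ``cross`` — a symmetrical plus shape (default 256x256) with four concave
  corners; tests whether a contour can enter concavities.
* ``noisy_circle`` — a disk (default 300x300) corrupted with additive
  Gaussian noise, mean 0 and variance 0.04 on the normalized [0, 1]
  intensity scale; tests robustness to noise.
* ``star`` — a star polygon (default 160x160) with deep concavities between
  its points.

All geometry is drawn by pixel-center membership tests so that ground truth
is exact and independently checkable by brute-force point-in-polygon
rasterization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .contour import rasterize_contour
from .errors import InvalidSpecError

__all__ = [
    "SyntheticSpec",
    "LabeledImage",
    "make_cross",
    "make_noisy_circle",
    "make_star",
    "generate",
    "cross_vertices",
    "star_vertices",
    "save_labeled_image",
]

_SHAPES = ("cross", "noisy_circle", "star")

# Geometry proportions, as fractions of the image side. The cross arms are a
# quarter of the side wide and three quarters long; the star spans radii
# 0.45/0.18 of the side. Fixed so that fixtures are deterministic.
CROSS_ARM_WIDTH_FRAC = 0.25
CROSS_ARM_LENGTH_FRAC = 0.75
CIRCLE_RADIUS_FRAC = 0.25
STAR_OUTER_FRAC = 0.45
STAR_INNER_FRAC = 0.18


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic fixture; identical specs reproduce
    bit-identical images.

    Intensities are given on the 8-bit [0, 255] scale; images are generated
    (and noise is applied) on the normalized [0, 1] scale.
    """

    shape: str
    side_px: int = 256
    foreground_intensity: float = 255.0
    background_intensity: float = 0.0
    noise_mean: float = 0.0
    noise_variance: float = 0.0
    star_points: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise InvalidSpecError(f"unknown shape {self.shape!r}; expected one of {_SHAPES}")
        if self.side_px < 32:
            raise InvalidSpecError("side_px must be at least 32")
        for name in ("foreground_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise InvalidSpecError(f"{name} must lie in [0, 255], got {v}")
        if self.noise_variance < 0:
            raise InvalidSpecError("noise_variance must be non-negative")
        if self.star_points < 3:
            raise InvalidSpecError("star_points must be at least 3")
        if self.seed < 0:
            raise InvalidSpecError("seed must be non-negative")


@dataclass(frozen=True)
class LabeledImage:
    """A generated image together with its exact ground-truth mask."""

    image: np.ndarray  # float in [0, 1]
    truth_mask: np.ndarray  # uint8 in {0, 1}
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise InvalidSpecError("image and truth_mask dimensions differ")


def _center(side: int) -> float:
    # Pixel centers at integer coordinates -> geometric image center.
    return (side - 1) / 2.0


def cross_vertices(side: int) -> np.ndarray:
    """The 12-gon outlining the plus shape, as (x, y) rows in pixel coordinates.

    Exposed so the rasterization can be cross-checked against an independent
    point-in-polygon test.
    """
    c = _center(side)
    hw = CROSS_ARM_WIDTH_FRAC * side / 2.0
    hl = CROSS_ARM_LENGTH_FRAC * side / 2.0
    return np.array(
        [
            (c - hw, c - hl), (c + hw, c - hl), (c + hw, c - hw), (c + hl, c - hw),
            (c + hl, c + hw), (c + hw, c + hw), (c + hw, c + hl), (c - hw, c + hl),
            (c - hw, c + hw), (c - hl, c + hw), (c - hl, c - hw), (c - hw, c - hw),
        ]
    )


def star_vertices(side: int, points: int) -> np.ndarray:
    """Alternating outer/inner vertices of the star polygon, first point up."""
    c = _center(side)
    r_out = STAR_OUTER_FRAC * side
    r_in = STAR_INNER_FRAC * side
    angles = -np.pi / 2 + np.arange(2 * points) * np.pi / points
    radii = np.where(np.arange(2 * points) % 2 == 0, r_out, r_in)
    return np.column_stack([c + radii * np.cos(angles), c + radii * np.sin(angles)])


def _two_level(mask: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    fg = spec.foreground_intensity / 255.0
    bg = spec.background_intensity / 255.0
    return np.where(mask.astype(bool), fg, bg).astype(float)


def make_cross(spec: SyntheticSpec) -> LabeledImage:
    """Centered plus shape, symmetric under 90-degree rotation about the center."""
    if spec.shape != "cross":
        raise InvalidSpecError("make_cross requires shape='cross'")
    if CROSS_ARM_WIDTH_FRAC * spec.side_px < 3:
        raise InvalidSpecError("side_px too small to draw cross arms >= 3 px wide")
    s = spec.side_px
    c = _center(s)
    hw = CROSS_ARM_WIDTH_FRAC * s / 2.0
    hl = CROSS_ARM_LENGTH_FRAC * s / 2.0
    xs, ys = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float))
    dx, dy = np.abs(xs - c), np.abs(ys - c)
    mask = ((dx <= hw) & (dy <= hl)) | ((dy <= hw) & (dx <= hl))
    return LabeledImage(_two_level(mask, spec), mask.astype(np.uint8), spec)


def make_noisy_circle(spec: SyntheticSpec) -> LabeledImage:
    """Centered disk of radius side/4 with additive Gaussian intensity noise.

    Noise is drawn as N(noise_mean, noise_variance) on the normalized [0, 1]
    scale, added to the clean two-level image and clipped back to [0, 1]. The
    ground-truth mask is the noise-free disk.
    """
    if spec.shape != "noisy_circle":
        raise InvalidSpecError("make_noisy_circle requires shape='noisy_circle'")
    s = spec.side_px
    c = _center(s)
    radius = CIRCLE_RADIUS_FRAC * s
    xs, ys = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float))
    mask = (xs - c) ** 2 + (ys - c) ** 2 <= radius**2
    clean = _two_level(mask, spec)
    if spec.noise_variance > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(spec.noise_mean, np.sqrt(spec.noise_variance), clean.shape)
        image = np.clip(clean + noise, 0.0, 1.0)
    else:
        image = clean
    return LabeledImage(image, mask.astype(np.uint8), spec)


def make_star(spec: SyntheticSpec) -> LabeledImage:
    """Centered star polygon with ``star_points`` outer and inner vertices."""
    if spec.shape != "star":
        raise InvalidSpecError("make_star requires shape='star'")
    verts = star_vertices(spec.side_px, spec.star_points)
    mask = rasterize_contour(verts, (spec.side_px, spec.side_px))
    return LabeledImage(_two_level(mask, spec), mask, spec)


def generate(spec: SyntheticSpec) -> LabeledImage:
    """Dispatch on ``spec.shape``."""
    maker = {"cross": make_cross, "noisy_circle": make_noisy_circle, "star": make_star}
    return maker[spec.shape](spec)


def save_labeled_image(labeled: LabeledImage, outdir: str | Path, stem: str | None = None) -> dict:
    """Write 8-bit grayscale PNG image, binary-mask PNG, and a spec JSON sidecar.

    Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or labeled.spec.shape
    paths = {
        "image": outdir / f"{stem}.png",
        "mask": outdir / f"{stem}_mask.png",
        "spec": outdir / f"{stem}_spec.json",
    }
    iio.imwrite(paths["image"], np.round(labeled.image * 255).astype(np.uint8))
    iio.imwrite(paths["mask"], (labeled.truth_mask * 255).astype(np.uint8))
    meta = asdict(labeled.spec)
    meta["rng"] = "numpy.random.default_rng(seed), PCG64"
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
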
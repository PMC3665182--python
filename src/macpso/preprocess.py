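"""Preprocessing chain: median denoising, Canny edges, Euclidean distance map.

The chain turns a grayscale image into the *distance potential surface* the
segmentation optimizes over: each pixel of the distance map holds the exact
Euclidean distance (in pixel units) to the nearest detected edge pixel, so
object boundaries are the zero-valued valleys of a height field.

Coordinate convention (package-wide): ``(x, y) = (column, row)``, 0-based,
pixel centers at integer coordinates. Arrays are indexed ``[row, col]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature

from .errors import InvalidParameterError, NoEdgesError, OutOfDomainError

__all__ = [
    "CannyParams",
    "median_filter",
    "canny_edges",
    "distance_map",
    "sample_surface",
    "preprocess",
    "load_image",
    "save_distance_map",
    "save_edge_map",
]

DEFAULT_MEDIAN_WINDOW = 3


@dataclass(frozen=True)
class CannyParams:
    """Canny edge-detector parameters.

    ``t_low``/``t_high`` are hysteresis thresholds stated on the 8-bit
    (0–255) central-difference gradient-magnitude scale and rescaled
    internally to the detector's working units.
    """

    sigma: float = 1.3
    t_low: float = 10.0
    t_high: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if self.t_low < 0:
            raise InvalidParameterError("t_low must be non-negative")
        if self.t_high <= self.t_low:
            raise InvalidParameterError("t_high must exceed t_low")


def median_filter(img: np.ndarray, window: int = DEFAULT_MEDIAN_WINDOW) -> np.ndarray:
    """Median-filter with a square window; borders handled by edge replication."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("median window must be an odd positive integer")
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise InvalidParameterError("image must be non-empty")
    if window == 1:
        return img.copy()
    return ndimage.median_filter(img, size=window, mode="nearest")


# skimage's Canny thresholds its unnormalized-Sobel magnitude, which is 8x
# the central-difference gradient of the (already smoothed) image; thresholds
# quoted on the 8-bit gradient scale therefore map through 8/255.
_SOBEL_PER_GRADIENT = 8.0


def canny_edges(img: np.ndarray, params: CannyParams = CannyParams()) -> np.ndarray:
    """Binary edge map via Gaussian smoothing, non-maximum suppression and
    hysteresis thresholding."""
    img = np.asarray(img, dtype=float)
    scale = _SOBEL_PER_GRADIENT / 255.0
    edges = feature.canny(
        img,
        sigma=params.sigma,
        low_threshold=params.t_low * scale,
        high_threshold=params.t_high * scale,
    )
    return edges.astype(np.uint8)


def distance_map(edges: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each pixel center to the nearest edge pixel."""
    edges = np.asarray(edges)
    if not edges.any():
        raise NoEdgesError("edge map is empty; cannot build a distance map")
    return ndimage.distance_transform_edt(edges == 0)


def sample_surface(surface: np.ndarray, x: float, y: float) -> float:
    """Bilinear interpolation of a 2D surface at continuous (x, y) = (col, row).

    Exact at integer coordinates; raises ``OutOfDomainError`` outside
    ``[0, width-1] x [0, height-1]``.
    """
    h, w = surface.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfDomainError(f"({x}, {y}) outside image domain {w}x{h}")
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    top = (1 - fx) * surface[y0, x0] + fx * surface[y0, x1]
    bot = (1 - fx) * surface[y1, x0] + fx * surface[y1, x1]
    return float((1 - fy) * top + fy * bot)


def preprocess(
    img: np.ndarray,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    canny: CannyParams = CannyParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full chain; returns (filtered image, edge map, distance map)."""
    filtered = median_filter(img, median_window)
    edges = canny_edges(filtered, canny)
    dmap = distance_map(edges)
    return filtered, edges, dmap


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image into the [0, 1] float working range.

    PNG/TIFF inputs are divided by the full-scale value of their bit depth;
    DICOM slices get rescale slope/intercept applied, then min-max
    normalization. Multichannel inputs are averaged to one channel.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        full_scale = 65535.0 if arr.max() > 255 else 255.0
        arr = arr / full_scale
    return arr


def save_distance_map(dmap: np.ndarray, path: str | Path) -> None:
    """Write the distance map as a 32-bit float TIFF for inspection."""
    import tifffile

    tifffile.imwrite(str(path), dmap.astype(np.float32))


def save_edge_map(edges: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(edges) * 255).astype(np.uint8))
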
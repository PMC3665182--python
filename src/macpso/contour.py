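"""Closed contours: the common output representation of both segmentation methods.

A contour is an ordered sequence of snaxels (control points) in (x, y) =
(column, row) coordinates, implicitly closed: the last point connects back to
the first. Pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np

from .errors import InvalidParameterError

__all__ = ["Contour", "rasterize_contour"]


@dataclass(frozen=True)
class Contour:
    """Closed polygonal contour of ``n >= 3`` snaxels.

    Parameters
    ----------
    points : (n, 2) float array
        Snaxel coordinates as (x, y) rows. The polygon is closed implicitly.
    """

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("contour points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise InvalidParameterError("a closed contour needs at least 3 snaxels")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError("contour coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str | FsPath) -> None:
        """Write snaxels as ``x,y`` rows with a ``closed=true`` header comment."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# closed=true\n")
            fh.write("x,y\n")
            for px, py in self.points:
                fh.write(f"{px!r},{py!r}\n")

    @classmethod
    def from_csv(cls, path: str | FsPath) -> "Contour":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("x,"):
                    continue
                sx, sy = line.split(",")
                rows.append((float(sx), float(sy)))
        return cls(np.asarray(rows, dtype=float))

    def to_json(self, path: str | FsPath) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"closed": True, "points": self.points.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | FsPath) -> "Contour":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["points"], dtype=float))


def rasterize_contour(contour: Contour | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill the interior of a closed contour on a pixel grid.

    A pixel belongs to the mask when its center lies inside the closed
    polygon under the even-odd rule (horizontal ray casting). For the
    radially parameterized polygons produced here (vertices ordered by angle
    about an interior origin) the polygon is simple, so the even-odd and
    winding fill rules coincide.

    Parameters
    ----------
    contour : Contour or (n, 2) array of (x, y) vertices
    shape : (height, width) of the target grid

    Returns
    -------
    (height, width) uint8 mask with values in {0, 1}.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = np.zeros((h, w), dtype=bool)
    x0, y0 = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for ex0, ey0, ex1, ey1 in zip(x0, y0, x1, y1):
        if ey0 == ey1:
            continue  # horizontal edges never cross the test ray
        straddles = (ey0 <= ys) != (ey1 <= ys)
        x_cross = ex0 + (ys - ey0) * (ex1 - ex0) / (ey1 - ey0)
        inside ^= straddles & (xs < x_cross)
    return inside.astype(np.uint8)
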
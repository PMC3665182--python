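"""Sequential-series segmentation and contour-stack surface reconstruction.

A series of slices sharing one origin and one parameter set is segmented
slice by slice (per-slice seed = base seed + slice index, so a series run is
reproducible yet slices are not forced onto identical particle trajectories).
Because the snaxel count depends only on the sectioning parameter g, every
slice yields a contour with the same number of points, and corresponding
snaxels share a section index (angle). Stacking the contours at a given
inter-slice spacing and triangulating each quad between adjacent slices
produces a closed tube: (#slices)·N vertices and (#slices−1)·2N triangles.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contour import Contour
from .core import PSOParams, SegmentationResult, run_macpso
from .errors import InvalidParameterError, InvalidStackError, NoEdgesError, ShapeMismatchError
from .preprocess import DEFAULT_MEDIAN_WINDOW, CannyParams, load_image

__all__ = [
    "SeriesSpec",
    "ContourStack",
    "segment_series",
    "triangulate_stack",
    "write_obj",
]

logger = logging.getLogger("macpso")


@dataclass(frozen=True)
class SeriesSpec:
    """One origin and parameter set propagated across an ordered image series."""

    image_paths: list
    origin: tuple[float, float]
    slice_spacing: float = 1.0
    params: PSOParams = PSOParams()
    canny: CannyParams = CannyParams()
    median_window: int = DEFAULT_MEDIAN_WINDOW

    def __post_init__(self) -> None:
        if len(self.image_paths) < 1:
            raise InvalidParameterError("a series needs at least one image")
        if self.slice_spacing <= 0:
            raise InvalidParameterError("slice_spacing must be positive")


@dataclass(frozen=True)
class ContourStack:
    """Ordered contours with identical snaxel counts, ready for meshing."""

    contours: list[Contour]
    slice_spacing: float

    def __post_init__(self) -> None:
        counts = {len(c) for c in self.contours}
        if len(counts) > 1:
            raise InvalidStackError(f"snaxel counts differ across slices: {sorted(counts)}")


def segment_series(spec: SeriesSpec, images: list[np.ndarray] | None = None) -> list[SegmentationResult | None]:
    """Segment every slice with the shared origin and parameters.

    ``images`` may carry pre-loaded arrays (same order as ``image_paths``);
    otherwise slices are read from disk. A slice whose edge map comes out
    empty is recorded as ``None`` and the series continues; slices with
    mismatched dimensions abort the run.
    """
    if images is None:
        images = [load_image(p) for p in spec.image_paths]
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"series images differ in size: {sorted(shapes)}")
    results: list[SegmentationResult | None] = []
    base_seed = spec.params.seed
    for i, img in enumerate(images):
        slice_params = PSOParams(**{**spec.params.__dict__, "seed": base_seed + i})
        t0 = time.perf_counter()
        try:
            res = run_macpso(
                img,
                origin=spec.origin,
                params=slice_params,
                canny=spec.canny,
                median_window=spec.median_window,
            )
        except NoEdgesError:
            logger.warning("slice %d: empty edge map, skipped", i)
            results.append(None)
            continue
        dt = time.perf_counter() - t0
        logger.info(
            "slice %d: %d iterations, final mean gbest fitness %.4f, %.3f s",
            i, res.iterations_run, res.fitness_trace[-1], dt,
        )
        results.append(res)
    return results


def triangulate_stack(stack: ContourStack) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a contour stack into a surface mesh.

    Vertex (i, j) is snaxel j of slice i at height ``i * slice_spacing``.
    Each quad between matching snaxel pairs of adjacent slices splits into
    two triangles, so the mesh has (#slices)·N vertices and
    (#slices−1)·2N faces; every interior edge is shared by exactly two faces.

    Returns ``(vertices, faces)`` as float (V, 3) and int (F, 3) arrays.
    """
    contours = stack.contours
    if len(contours) < 2:
        raise InvalidStackError("meshing needs at least 2 contours")
    n = len(contours[0])
    vertices = np.vstack(
        [
            np.column_stack([c.points, np.full(n, i * stack.slice_spacing)])
            for i, c in enumerate(contours)
        ]
    )
    faces = []
    for i in range(len(contours) - 1):
        base0, base1 = i * n, (i + 1) * n
        for j in range(n):
            jn = (j + 1) % n
            v00, v01 = base0 + j, base0 + jn
            v10, v11 = base1 + j, base1 + jn
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    return vertices, np.asarray(faces, dtype=int)


def write_obj(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Write the mesh as Wavefront OBJ (1-based face indices)."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in vertices:
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
        for a, b, c in faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")
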
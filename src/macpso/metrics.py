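"""Segmentation validation metrics.

Region metrics compare a computed segmentation A against a reference B as
pixel sets: Jaccard |A∩B|/|A∪B|, Dice 2|A∩B|/(|A|+|B|), and the Hausdorff
distance. The printed Hausdorff form max_{a∈A} min_{b∈B} ||a−b|| is the
*directed* variant; the symmetric variant (max of both directions) is the
conventional headline number and both are reported.

Area is the foreground pixel count; perimeter is the length of the
8-connected boundary chain (unit steps for edge moves, sqrt(2) for
diagonals), obtained by Moore boundary tracing of every component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff
from skimage import measure

from .errors import ShapeMismatchError, UndefinedMetricError

__all__ = [
    "MetricsReport",
    "jaccard",
    "dice",
    "hausdorff",
    "area",
    "perimeter",
    "evaluate",
    "batch_evaluate",
]


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    return m.astype(bool)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return _as_mask(a), _as_mask(b)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; 1 for identical non-empty regions, 0 for disjoint."""
    a, b = _check_pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks empty")
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|)."""
    a, b = _check_pair(a, b)
    total = a.sum() + b.sum()
    if total == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return float(2.0 * np.logical_and(a, b).sum() / total)


def _coords(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([rows, cols]).astype(float)


def hausdorff(a: np.ndarray, b: np.ndarray, mode: str = "symmetric") -> float:
    """Hausdorff distance between the foreground pixel sets, in pixels.

    ``mode='directed'`` gives max_{a∈A} min_{b∈B} ||a−b||;
    ``mode='symmetric'`` the max of the two directed values.
    """
    a, b = _check_pair(a, b)
    if not a.any() or not b.any():
        raise UndefinedMetricError("Hausdorff undefined for an empty mask")
    ca, cb = _coords(a), _coords(b)
    d_ab = directed_hausdorff(ca, cb)[0]
    if mode == "directed":
        return float(d_ab)
    if mode != "symmetric":
        raise UndefinedMetricError(f"unknown Hausdorff mode {mode!r}")
    d_ba = directed_hausdorff(cb, ca)[0]
    return float(max(d_ab, d_ba))


def area(mask: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(_as_mask(mask).sum())


# Moore neighborhood in clockwise order starting north, as (dr, dc).
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_SQRT2 = math.sqrt(2.0)


def _trace_chain_length(mask: np.ndarray) -> float:
    """Chain-code length of the outer boundary of one 8-connected component."""
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    if rows.size <= 1:
        return 0.0
    first = np.lexsort((cols, rows))[0]  # topmost, then leftmost
    cur = (int(rows[first]), int(cols[first]))
    backtrack = 6  # the west neighbor of the start pixel is background

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    length = 0.0
    first_transition = None
    while True:
        hit = None
        for k in range(1, 9):
            j = (backtrack + k) % 8
            rr, cc = cur[0] + _MOORE[j][0], cur[1] + _MOORE[j][1]
            if is_fg(rr, cc):
                hit = (j, k, (rr, cc))
                break
        if hit is None:  # isolated pixel
            return 0.0
        j, k, nxt = hit
        transition = (cur, j)
        if first_transition is None:
            first_transition = transition
        elif transition == first_transition:
            break
        length += _SQRT2 if (_MOORE[j][0] != 0 and _MOORE[j][1] != 0) else 1.0
        # The neighbor scanned just before the hit is background and
        # 8-adjacent to the next pixel: it becomes the new backtrack.
        prev_j = (backtrack + k - 1) % 8
        pr, pc = cur[0] + _MOORE[prev_j][0], cur[1] + _MOORE[prev_j][1]
        backtrack = _MOORE.index((pr - nxt[0], pc - nxt[1]))
        cur = nxt
    return length


def perimeter(mask: np.ndarray) -> float:
    """Total chain-code boundary length over all 8-connected components.

    A single isolated pixel contributes 0.
    """
    mask = _as_mask(mask)
    if not mask.any():
        return 0.0
    labels = measure.label(mask, connectivity=2)
    total = 0.0
    for lab in range(1, labels.max() + 1):
        total += _trace_chain_length(labels == lab)
    return total


@dataclass(frozen=True)
class MetricsReport:
    """All metrics for one (computed A, reference B) pair."""

    jaccard: float
    dice: float
    hausdorff_directed_AB: float
    hausdorff_directed_BA: float
    hausdorff_symmetric: float
    area_A: int
    area_B: int
    perimeter_A: float
    perimeter_B: float


def evaluate(pred: np.ndarray, ref: np.ndarray) -> MetricsReport:
    """Compute the full metric panel for one mask pair."""
    a, b = _check_pair(np.asarray(pred), np.asarray(ref))
    d_ab = hausdorff(a, b, "directed")
    d_ba = hausdorff(b, a, "directed")
    return MetricsReport(
        jaccard=jaccard(a, b),
        dice=dice(a, b),
        hausdorff_directed_AB=d_ab,
        hausdorff_directed_BA=d_ba,
        hausdorff_symmetric=max(d_ab, d_ba),
        area_A=area(a),
        area_B=area(b),
        perimeter_A=perimeter(a),
        perimeter_B=perimeter(b),
    )


def batch_evaluate(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Metric table over (name, pred, ref) triples, with an ``average`` row."""
    rows = []
    for name, pred, ref in pairs:
        rep = evaluate(pred, ref)
        rows.append({"name": name, **rep.__dict__})
    df = pd.DataFrame(rows).set_index("name")
    df.loc["average"] = df.mean(numeric_only=True)
    return df
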
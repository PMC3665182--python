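"""Greedy active contour model (snake): the traditional baseline.

A snake is a closed chain of snaxels p_1..p_n. Each greedy iteration moves
every snaxel to the candidate q in its (2w+1)x(2w+1) searching window that
minimizes the local energy

    E(q) = 1/2 [ alpha * |q - p_{i-1}|^2 + beta * |p_{i-1} - 2q + p_{i+1}|^2 ]
           + E_ext(q)

where the tension term (alpha) penalizes stretching, the rigidity term
(beta) penalizes bending, and the external term couples the snake to the
image. Two external energies are supported:

* ``gradient`` — E_ext = -(gamma/2) |grad S|^2, the classical intensity-edge
  attraction, for running directly on a grayscale image;
* ``height`` — E_ext = gamma * S, the distance-potential form, for running
  on a Euclidean distance map whose valleys are the object edges. (On a
  distance map the gradient magnitude is ~1 almost everywhere and vanishes
  exactly at the valley bottom, so the gradient form would repel the snake
  from edges; the height form is the meaningful coupling there.)

Updates are simultaneous (Jacobi-style): the neighbors entering a snaxel's
energy are the pre-step positions, so the step is order-independent. The
energy reported for a step is the minimized sum of Eq-style local terms
under those fixed neighbors, which is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour, rasterize_contour
from .core import SegmentationResult
from .errors import InvalidParameterError, OutOfDomainError

__all__ = [
    "ACMParams",
    "EnergySurface",
    "internal_energy",
    "external_energy",
    "greedy_step",
    "greedy_step_detailed",
    "run_acm",
    "Contour",
]


@dataclass(frozen=True)
class ACMParams:
    """Greedy-snake parameters; defaults alpha=0.01, beta=0.9, gamma=0.05 and
    a 5x5 searching window."""

    alpha: float = 0.01
    beta: float = 0.9
    gamma: float = 0.05
    window_radius: int = 2
    max_iterations: int = 100
    stable_fraction: float = 0.05
    surface_mode: str = "gradient"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise InvalidParameterError("alpha, beta, gamma must be non-negative")
        if self.window_radius < 1:
            raise InvalidParameterError("window_radius must be >= 1")
        if self.max_iterations < 0:
            raise InvalidParameterError("max_iterations must be >= 0")
        if not 0 < self.stable_fraction <= 1:
            raise InvalidParameterError("stable_fraction must be in (0, 1]")
        if self.surface_mode not in ("gradient", "height"):
            raise InvalidParameterError("surface_mode must be 'gradient' or 'height'")


class EnergySurface:
    """A 2D surface with lazily cached central-difference gradient fields,
    so repeated candidate evaluations do not recompute the gradient."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("surface must be 2D")
        self._grad: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def grad(self) -> tuple[np.ndarray, np.ndarray]:
        """(d/dy, d/dx) central-difference gradient fields."""
        if self._grad is None:
            gy, gx = np.gradient(self.values)
            self._grad = (gy, gx)
        return self._grad


def _bilinear_many(field: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized bilinear sampling; callers guarantee in-bounds coordinates."""
    h, w = field.shape
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx, fy = xs - x0, ys - y0
    top = (1 - fx) * field[y0, x0] + fx * field[y0, x1]
    bot = (1 - fx) * field[y1, x0] + fx * field[y1, x1]
    return (1 - fy) * top + fy * bot


def internal_energy(prev, cand, next_, alpha: float, beta: float) -> float:
    """Tension + rigidity energy of one snaxel candidate against its fixed
    neighbors: 1/2 [alpha |cand-prev|^2 + beta |prev - 2 cand + next|^2]."""
    prev = np.asarray(prev, float)
    cand = np.asarray(cand, float)
    next_ = np.asarray(next_, float)
    stretch = np.sum((cand - prev) ** 2)
    bend = np.sum((prev - 2 * cand + next_) ** 2)
    return float(0.5 * (alpha * stretch + beta * bend))


def external_energy(surface, cand, gamma: float, mode: str = "gradient") -> float:
    """Image coupling at one candidate point.

    ``gradient``: -(gamma/2) |grad S(cand)|^2 with bilinear-sampled
    central-difference gradients. ``height``: gamma * S(cand).
    """
    es = surface if isinstance(surface, EnergySurface) else EnergySurface(surface)
    h, w = es.shape
    x, y = float(cand[0]), float(cand[1])
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfDomainError(f"candidate ({x}, {y}) outside surface {w}x{h}")
    xs, ys = np.array([x]), np.array([y])
    if mode == "height":
        return float(gamma * _bilinear_many(es.values, xs, ys)[0])
    gy, gx = es.grad
    gxv = _bilinear_many(gx, xs, ys)[0]
    gyv = _bilinear_many(gy, xs, ys)[0]
    return float(-(gamma / 2.0) * (gxv**2 + gyv**2))


def _window_offsets(w: int) -> np.ndarray:
    """Row-major (2w+1)^2 offsets; the center (current position) is index
    ``(2w+1)^2 // 2``."""
    rng = np.arange(-w, w + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    return np.column_stack([dx.ravel(), dy.ravel()]).astype(float)


def greedy_step_detailed(
    contour: Contour, surface, params: ACMParams
) -> tuple[Contour, int, float, float]:
    """One simultaneous greedy sweep.

    Returns ``(new_contour, moved_count, energy_before, energy_after)`` where
    the energies are the snake sums of local terms evaluated with the
    pre-step neighbors (before: at the current positions; after: at the
    per-snaxel minima). ``energy_after <= energy_before`` always.

    Window candidates falling outside the image are clipped to the border.
    Ties prefer the snaxel's current position, then the lowest row-major
    window index.
    """
    es = surface if isinstance(surface, EnergySurface) else EnergySurface(surface)
    h, w_img = es.shape
    pts = contour.points
    n = len(pts)
    offs = _window_offsets(params.window_radius)
    k_center = offs.shape[0] // 2
    if params.surface_mode == "height":
        ext_field = None
    else:
        gy, gx = es.grad
        ext_field = (gx, gy)

    new_pts = np.empty_like(pts)
    moved = 0
    e_before = 0.0
    e_after = 0.0
    for i in range(n):
        prev_pt = pts[i - 1]
        next_pt = pts[(i + 1) % n]
        cur = pts[i]
        cands = cur + offs
        np.clip(cands[:, 0], 0.0, w_img - 1.0, out=cands[:, 0])
        np.clip(cands[:, 1], 0.0, h - 1.0, out=cands[:, 1])
        stretch = np.sum((cands - prev_pt) ** 2, axis=1)
        bend = np.sum((prev_pt - 2 * cands + next_pt) ** 2, axis=1)
        e_int = 0.5 * (params.alpha * stretch + params.beta * bend)
        if params.surface_mode == "height":
            e_ext = params.gamma * _bilinear_many(es.values, cands[:, 0], cands[:, 1])
        else:
            gxv = _bilinear_many(ext_field[0], cands[:, 0], cands[:, 1])
            gyv = _bilinear_many(ext_field[1], cands[:, 0], cands[:, 1])
            e_ext = -(params.gamma / 2.0) * (gxv**2 + gyv**2)
        energy = e_int + e_ext
        k_min = int(np.argmin(energy))
        k = k_center if energy[k_center] <= energy[k_min] else k_min
        e_before += float(energy[k_center])
        e_after += float(energy[k])
        new_pts[i] = cands[k]
        if not np.array_equal(cands[k], cur):
            moved += 1
    return Contour(new_pts), moved, e_before, e_after


def greedy_step(contour: Contour, surface, params: ACMParams) -> tuple[Contour, int]:
    """One greedy sweep; returns the updated contour and how many snaxels moved."""
    new_contour, moved, _, _ = greedy_step_detailed(contour, surface, params)
    return new_contour, moved


def run_acm(surface, init: Contour, params: ACMParams = ACMParams()) -> SegmentationResult:
    """Iterate greedy sweeps until fewer than ``stable_fraction`` of snaxels
    move, or ``max_iterations`` is reached.

    ``surface`` is a grayscale image (``surface_mode='gradient'``) or a
    distance map (``surface_mode='height'``). The per-iteration minimized
    snake energy is recorded in ``fitness_trace``.
    """
    es = EnergySurface(np.asarray(surface, dtype=float) if not isinstance(surface, EnergySurface) else surface.values)
    h, w = es.shape
    pts = init.points
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w - 1) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h - 1):
        raise OutOfDomainError("initial contour leaves the image domain")
    contour = init
    n = len(init)
    trace: list[float] = []
    iterations_run = 0
    for _ in range(params.max_iterations):
        contour, moved, _, e_after = greedy_step_detailed(contour, es, params)
        trace.append(e_after)
        iterations_run += 1
        if moved / n < params.stable_fraction:
            break
    params_used = {
        "method": "acm_greedy",
        "alpha": params.alpha,
        "beta": params.beta,
        "gamma": params.gamma,
        "window_radius": params.window_radius,
        "max_iterations": params.max_iterations,
        "stable_fraction": params.stable_fraction,
        "surface_mode": params.surface_mode,
        "n_snaxels": n,
    }
    mask = rasterize_contour(contour, es.shape)
    return SegmentationResult(contour, mask, trace, params_used, iterations_run, "acm_greedy")
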
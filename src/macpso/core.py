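"""Multiple active contours driven by particle swarm optimization (MACPSO).

The plane around a user-chosen origin inside the object is partitioned into
``N`` angular sections. Each of the ``n_snakes`` concentric initial contours
contributes one snaxel per section, and the snaxels of a section form one
particle swarm whose particles live on the section's center ray: a particle's
state is a single radial coordinate ``r``, its Cartesian position
``origin + r * (cos(theta_c), sin(theta_c))``.

Each swarm minimizes the distance potential surface — the Euclidean distance
map of the edge image — along its ray with the standard PSO velocity update

    v <- phi * v + kappa * r1 * (pbest - r) + kappa * r2 * (gbest - r)
    r <- r + v,        r1, r2 ~ U(0, 1)

with inertia weight ``phi`` and learning factor ``kappa``. Because every
section optimizes independently, concave stretches of the boundary are
reached as easily as convex ones. The segmentation is the closed polygon
joining each section's best particle (gbest) in angular order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import filters, measure

from .contour import Contour, rasterize_contour
from .errors import (
    InvalidInitializationError,
    InvalidOriginError,
    InvalidParameterError,
)
from .preprocess import (
    DEFAULT_MEDIAN_WINDOW,
    CannyParams,
    preprocess,
    sample_surface,
)

__all__ = [
    "PSOParams",
    "PolarLayout",
    "Particle",
    "Swarm",
    "SegmentationResult",
    "sections_from_g",
    "build_layout",
    "init_swarms",
    "fitness",
    "pso_step",
    "constrain_particle",
    "run_macpso",
    "auto_origin",
]

#: Minimum mean-gbest improvement that still counts as progress.
STALL_TOLERANCE = 1e-6
#: Consecutive stalled iterations that trigger early stopping.
STALL_PATIENCE = 3
#: Automatic initial contours span this radial fraction range of each ray.
AUTO_RADIUS_RANGE = (0.15, 0.9)


def sections_from_g(g: float, g_units: str = "centiradian") -> int:
    """Number of polar sections (= snaxels of the output contour) for a
    sectioning parameter ``g``.

    With the default ``centiradian`` units each section spans ``0.01 * g``
    radians, so ``N = round(2*pi / (0.01*g))`` — g=10 gives 63 sections,
    g=15 gives 42. The ``degree`` reading (``N = round(360/g)``) is offered
    as an alternative convention.
    """
    if g <= 0:
        raise InvalidParameterError("g must be positive")
    if g_units == "centiradian":
        n = round(2 * math.pi / (0.01 * g))
    elif g_units == "degree":
        n = round(360.0 / g)
    else:
        raise InvalidParameterError(f"unknown g_units {g_units!r}")
    if n < 3:
        raise InvalidParameterError(f"g={g} yields fewer than 3 sections")
    return n


@dataclass(frozen=True)
class PSOParams:
    """Swarm-optimization settings. Defaults are the standard operating point
    for single-object segmentation: 20 iterations, inertia 0.8, learning
    factor 0.5, 15 snakes, g=15 (42 snaxels)."""

    iterations: int = 20
    inertia: float = 0.8
    learning_factor: float = 0.5
    n_snakes: int = 15
    g: float = 15.0
    g_units: str = "centiradian"
    init_shape: str = "circular"
    init_radii: Sequence[float] | None = None
    ellipse_aspect: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InvalidParameterError("iterations must be >= 1")
        if self.inertia < 0 or self.learning_factor < 0:
            raise InvalidParameterError("inertia and learning_factor must be >= 0")
        if self.n_snakes < 1:
            raise InvalidParameterError("n_snakes must be >= 1")
        if self.init_shape not in ("circular", "elliptical"):
            raise InvalidParameterError("init_shape must be 'circular' or 'elliptical'")
        if self.init_radii is not None and len(self.init_radii) != self.n_snakes:
            raise InvalidParameterError("init_radii must list one radius per snake")
        if self.ellipse_aspect <= 0:
            raise InvalidParameterError("ellipse_aspect must be positive")
        if self.seed < 0:
            raise InvalidParameterError("seed must be non-negative")
        sections_from_g(self.g, self.g_units)  # validates g


@dataclass(frozen=True)
class PolarLayout:
    """Origin plus an exact angular partition of [0, 2*pi) into N sections.

    ``section_center_angle[i] = (i + 1/2) * 2*pi / N``; section ``i`` covers
    the half-open interval ``[i * 2*pi/N, (i+1) * 2*pi/N)``. ``r_max[i]`` is
    the distance from the origin to the image border along the center ray.
    """

    origin_x: float
    origin_y: float
    g: float
    n_sections: int
    section_center_angle: np.ndarray = field(repr=False)
    section_edges: np.ndarray = field(repr=False)  # N+1 bin edges over [0, 2*pi]
    r_max: np.ndarray = field(repr=False)
    image_shape: tuple[int, int] = (0, 0)

    def section_of(self, angle: float) -> int:
        """Section index containing ``angle`` (wrapped into [0, 2*pi))."""
        a = angle % (2 * math.pi)
        idx = int(np.searchsorted(self.section_edges, a, side="right")) - 1
        return min(max(idx, 0), self.n_sections - 1)

    def position(self, section: int, r: float) -> tuple[float, float]:
        a = self.section_center_angle[section]
        return self.origin_x + r * math.cos(a), self.origin_y + r * math.sin(a)


def _ray_border_distance(ox: float, oy: float, angle: float, shape: tuple[int, int]) -> float:
    """Distance from (ox, oy) to the image rectangle border along ``angle``."""
    h, w = shape
    dx, dy = math.cos(angle), math.sin(angle)
    ts = []
    if dx > 1e-12:
        ts.append((w - 1 - ox) / dx)
    elif dx < -1e-12:
        ts.append(-ox / dx)
    if dy > 1e-12:
        ts.append((h - 1 - oy) / dy)
    elif dy < -1e-12:
        ts.append(-oy / dy)
    return min(ts)


def build_layout(
    origin: tuple[float, float], g: float, image_shape: tuple[int, int], g_units: str = "centiradian"
) -> PolarLayout:
    """Partition [0, 2*pi) about ``origin`` into ``sections_from_g(g)`` sections."""
    ox, oy = float(origin[0]), float(origin[1])
    h, w = image_shape
    if not (0 < ox < w - 1 and 0 < oy < h - 1):
        raise InvalidOriginError(f"origin ({ox}, {oy}) not strictly inside image {w}x{h}")
    n = sections_from_g(g, g_units)
    edges = np.linspace(0.0, 2 * math.pi, n + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    r_max = np.array([_ray_border_distance(ox, oy, a, image_shape) for a in centers])
    return PolarLayout(ox, oy, g, n, centers, edges, r_max, tuple(image_shape))


@dataclass
class Particle:
    """One candidate snaxel on a section's center ray."""

    section_index: int
    r: float
    v: float = 0.0
    fitness: float = math.inf
    pbest_r: float = 0.0
    pbest_fitness: float = math.inf


@dataclass
class Swarm:
    """All particles of one polar section plus the section's best solution."""

    section_index: int
    particles: list[Particle]
    gbest_r: float = 0.0
    gbest_fitness: float = math.inf


def fitness(dmap: np.ndarray, layout: PolarLayout, section: int, r: float) -> float:
    """Height of the distance potential surface at the particle's position.

    Lower is better; 0 is attained exactly on edge pixels. Positions outside
    the image evaluate to +inf so they can never become a personal best.
    """
    x, y = layout.position(section, r)
    h, w = dmap.shape
    if r < 0 or not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        return math.inf
    return sample_surface(dmap, x, y)


def constrain_particle(particle: Particle, layout: PolarLayout) -> Particle:
    """Clip the radius into the section's feasible interval [0, r_max];
    a clipped particle loses its velocity."""
    lo, hi = 0.0, float(layout.r_max[particle.section_index])
    if particle.r < lo:
        particle.r, particle.v = lo, 0.0
    elif particle.r > hi:
        particle.r, particle.v = hi, 0.0
    return particle


def _initial_radii(layout: PolarLayout, params: PSOParams, section: int) -> np.ndarray:
    a = layout.section_center_angle[section]
    if params.init_radii is not None:
        nominal = np.asarray(params.init_radii, dtype=float)
    else:
        lo, hi = AUTO_RADIUS_RANGE
        nominal = np.linspace(lo, hi, params.n_snakes) * layout.r_max[section]
    if params.init_shape == "elliptical":
        # Nominal radius is the semi-x axis; semi-y = aspect * semi-x.
        ax, bx = nominal, nominal * params.ellipse_aspect
        denom = np.sqrt((bx * math.cos(a)) ** 2 + (ax * math.sin(a)) ** 2)
        radii = np.where(denom > 0, ax * bx / np.maximum(denom, 1e-300), 0.0)
    else:
        radii = nominal
    return radii


def init_swarms(layout: PolarLayout, params: PSOParams, dmap: np.ndarray) -> list[Swarm]:
    """One swarm per section; particle ``k`` of every swarm belongs to the
    k-th concentric initial contour. Velocities start at zero, personal bests
    at the initial positions, gbest at the best initial personal best."""
    swarms: list[Swarm] = []
    for s in range(layout.n_sections):
        radii = _initial_radii(layout, params, s)
        if np.any(radii < 0) or np.any(radii > layout.r_max[s]):
            raise InvalidInitializationError(
                f"initial contour leaves the image in section {s} "
                f"(radii up to {radii.max():.2f}, r_max {layout.r_max[s]:.2f})"
            )
        particles = []
        for r in radii:
            f = fitness(dmap, layout, s, float(r))
            particles.append(
                Particle(section_index=s, r=float(r), v=0.0, fitness=f, pbest_r=float(r), pbest_fitness=f)
            )
        best = min(particles, key=lambda p: p.pbest_fitness)
        swarms.append(Swarm(s, particles, gbest_r=best.pbest_r, gbest_fitness=best.pbest_fitness))
    return swarms


def pso_step(
    swarm: Swarm,
    params: PSOParams,
    rng: np.random.Generator,
    dmap: np.ndarray,
    layout: PolarLayout,
) -> Swarm:
    """One synchronous PSO iteration for one swarm.

    Per particle: velocity and position update with fresh U(0,1) draws,
    feasibility clipping, fitness evaluation, and personal-best update;
    afterwards the swarm best is updated only if a better personal best
    appeared.
    """
    phi, kappa = params.inertia, params.learning_factor
    for p in swarm.particles:
        r1, r2 = rng.random(), rng.random()
        p.v = phi * p.v + kappa * r1 * (p.pbest_r - p.r) + kappa * r2 * (swarm.gbest_r - p.r)
        p.r = p.r + p.v
        constrain_particle(p, layout)
        p.fitness = fitness(dmap, layout, p.section_index, p.r)
        if p.fitness < p.pbest_fitness:
            p.pbest_r, p.pbest_fitness = p.r, p.fitness
    best = min(swarm.particles, key=lambda q: q.pbest_fitness)
    if best.pbest_fitness < swarm.gbest_fitness:
        swarm.gbest_r, swarm.gbest_fitness = best.pbest_r, best.pbest_fitness
    return swarm


@dataclass(frozen=True)
class SegmentationResult:
    """Output of a segmentation run (MACPSO or the greedy-snake baseline)."""

    contour: Contour
    mask: np.ndarray = field(repr=False)
    fitness_trace: list[float] = field(repr=False)
    params_used: dict = field(repr=False)
    iterations_run: int = 0
    method: str = "macpso"


def auto_origin(img: np.ndarray) -> tuple[float, float]:
    """Automatic origin: centroid of the largest connected component of the
    Otsu-thresholded (bright) foreground. Falls back to the image center for
    degenerate images."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if img.max() == img.min():
        return center
    binary = img > filters.threshold_otsu(img)
    if not binary.any():
        return center
    labels = measure.label(binary, connectivity=2)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    cy, cx = largest.centroid
    return float(cx), float(cy)


def run_macpso(
    img: np.ndarray,
    origin: tuple[float, float] | None = None,
    params: PSOParams = PSOParams(),
    canny: CannyParams = CannyParams(),
    median_window: int = DEFAULT_MEDIAN_WINDOW,
) -> SegmentationResult:
    """Segment one closed object.

    Pipeline: median filter -> Canny -> Euclidean distance map -> polar layout
    about ``origin`` (auto-detected when None) -> per-section PSO -> contour
    from the gbest of every section, in angular order.

    The run stops after ``params.iterations`` iterations, or earlier once the
    mean gbest fitness has improved by less than 1e-6 for 3 consecutive
    iterations. ``fitness_trace`` records the mean of all sections' gbest
    fitness after each iteration and is non-increasing by construction.
    """
    img = np.asarray(img, dtype=float)
    if origin is None:
        origin = auto_origin(img)
    _, edges, dmap = preprocess(img, median_window=median_window, canny=canny)
    layout = build_layout(origin, params.g, img.shape, params.g_units)
    swarms = init_swarms(layout, params, dmap)
    rng = np.random.default_rng(params.seed)

    trace: list[float] = []
    stall = 0
    iterations_run = 0
    for _ in range(params.iterations):
        for swarm in swarms:
            pso_step(swarm, params, rng, dmap, layout)
        mean_gbest = float(np.mean([s.gbest_fitness for s in swarms]))
        if trace and trace[-1] - mean_gbest < STALL_TOLERANCE:
            stall += 1
        else:
            stall = 0
        trace.append(mean_gbest)
        iterations_run += 1
        if stall >= STALL_PATIENCE:
            break

    points = np.array([layout.position(s.section_index, s.gbest_r) for s in swarms])
    contour = Contour(points)
    mask = rasterize_contour(contour, img.shape)
    params_used = {
        "method": "macpso",
        "origin": [layout.origin_x, layout.origin_y],
        "g": params.g,
        "g_units": params.g_units,
        "n_sections": layout.n_sections,
        "n_snakes": params.n_snakes,
        "iterations": params.iterations,
        "inertia": params.inertia,
        "learning_factor": params.learning_factor,
        "init_shape": params.init_shape,
        "seed": params.seed,
        "median_window": median_window,
        "canny": {"sigma": canny.sigma, "t_low": canny.t_low, "t_high": canny.t_high},
    }
    return SegmentationResult(contour, mask, trace, params_used, iterations_run, "macpso")
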
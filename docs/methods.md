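# Methods

## Problem and approach

The package segments a single closed object in a 2D grayscale image — the
motivating application is the heart or left ventricle in a CT/MR slice —
given one point (the *origin*) inside the object. Classical parametric
active contours (snakes) minimize a sum of internal (tension + rigidity)
and image-coupling energies, but a greedy snake started far from the
boundary stalls in local minima and cannot enter concavities. The method
implemented here replaces the coupled curve evolution with many independent
one-dimensional searches:

1. **Preprocessing.** Median filter (3×3) → Canny edge detection →
   exact Euclidean distance transform of the edge map. The resulting
   *distance potential surface* D(x, y) is zero exactly on detected edges
   and grows linearly away from them.
2. **Polar sectioning.** The plane around the origin is split into N
   angular sections. N is derived from the sectioning parameter g by
   N = round(2π / (0.01·g)), i.e. g is an angular step in hundredths of a
   radian: g = 10 → 63 sections, g = 15 → 42. (A literal degrees reading,
   N = round(360/g), is available via `g_units="degree"`.)
3. **Per-section PSO.** Each of the `n_snakes` concentric initial contours
   contributes one point per section; those points form the section's
   particle swarm. A particle's state is a single radius r along the
   section's center ray, updated by the standard PSO rule
   v ← φ·v + κ·r₁·(pbest − r) + κ·r₂·(gbest − r), r ← r + v, with
   r₁, r₂ ~ U(0,1) drawn fresh each update. The fitness of a particle is
   simply D at its position (bilinear interpolation): lower is better, zero
   means "on an edge". Radii are clipped to [0, r_max] of the ray (image
   border), with velocity reset on clipping.
4. **Contour assembly.** After the iteration budget (or earlier, see
   stopping below), the per-section best particles are joined in angular
   order into a closed polygon; its even-odd rasterization is the output
   mask.

Because every section is optimized independently, a concave boundary
segment is found exactly as easily as a convex one — each ray only needs to
locate the nearest edge crossing, not fight the curve's global smoothness
constraints.

## Parameters

| name | default | meaning |
|---|---|---|
| `g` | 15 | angular step in centiradians; N = round(2π/0.01g) snaxels |
| `n_snakes` | 15 | concentric initial contours = particles per swarm |
| `iterations` | 20 | PSO iteration cap |
| `inertia` (φ) | 0.8 | velocity memory; constant, no decay |
| `learning_factor` (κ) | 0.5 | weight of the pbest/gbest attraction terms |
| `init_shape` | circular | circular or elliptical initial contours |
| `seed` | 0 | PCG64 stream for all U(0,1) draws |
| `median_window` | 3 | median denoising window |
| `canny.sigma` | 1.3 | Gaussian scale of the edge detector |
| `canny.t_low/t_high` | 10 / 30 | hysteresis thresholds, 8-bit gradient scale |
| ACM `alpha/beta/gamma` | 0.01 / 0.9 / 0.05 | snake tension/rigidity/external weight |
| ACM `window_radius` | 2 | 5×5 greedy searching window |

Automatic initial radii are evenly spaced over [0.15, 0.9]·r_max of each
ray. γ does not appear in the swarm fitness: a positive scale factor on D
changes no argmin, so it is kept only in the snake baseline's energy.

## Numerical and design choices

**Canny threshold scale.** The hysteresis thresholds are quoted on the
8-bit central-difference gradient scale (a full 0→255 step edge smoothed at
σ = 1.3 peaks near 78; thresholds 10/30 sit well under it). Internally the
detector (scikit-image) thresholds an *unnormalized Sobel* magnitude, which
is 8× the central-difference gradient of the smoothed image, so thresholds
are mapped through 8/255. With this mapping the default thresholds cleanly
separate the noise floor from true edges on the noisy-disk fixture; a naive
1/255 mapping floods the edge map with noise responses.

**Fitness surface.** The swarms minimize the distance map directly rather
than a gradient-magnitude energy. On a distance map |∇D| ≈ 1 almost
everywhere and vanishes exactly in the valley, so a −|∇D|² energy would
make edges *maxima*; the height of D is the meaningful objective. For the
same reason the greedy-snake baseline has two external-energy modes:
`gradient` (−γ/2·|∇S|², the classical form, for raw intensity images) and
`height` (γ·S, the distance-potential form, used whenever the baseline runs
on the shared distance map for a like-for-like comparison).

**Greedy-step energy bookkeeping.** Greedy sweeps update all snaxels
simultaneously against their pre-step neighbors (order independence). The
per-step energy reported in the trace is the sum of per-snaxel minimized
local terms under those fixed neighbors; this quantity cannot increase
within a step and is what the monotonicity tests check. The full
configuration energy across steps usually also decreases but is not
certified — with the default weights (β = 0.9 dominating γ = 0.05) the
simultaneous midpoint attraction in fact shrinks the snake slowly through
weak distance valleys, the classical collapse pathology of greedy snakes
and the reason the baseline underperforms on every fixture.

**Stopping.** PSO: iteration cap, or mean-of-gbest improvement below 1e−6
for 3 consecutive iterations. Since gbest only updates on strict
improvement, the mean-gbest trace is non-increasing by construction.
Greedy snake: sweep cap, or fewer than `stable_fraction` (default 5%) of
snaxels moving.

**Tie-breaking.** The greedy argmin prefers the snaxel's current position,
then the lowest row-major window index — this prevents oscillation on
plateaus. PSO particles whose update leaves the feasible radial interval
are clipped and lose their velocity ("ignore improper particles" realized
without stalling the swarm).

**Rasterization.** Mask filling uses an even-odd horizontal ray cast
against pixel centers, written in-package (the obvious library routine,
matplotlib's `Path.contains_points` on closed paths, misclassifies interior
points near vertices and is used only as a cross-check oracle in the tests
via its implicit-closure form).

**Automatic origin.** When no origin is given: Otsu threshold, largest
8-connected bright component, centroid. This suffices for the synthetic
fixtures; clinical slices generally need the interactive origin.

## Synthetic fixtures

The generators produce the three standard robustness fixtures, each with an
exact ground-truth mask and a 5 px border margin:

* **cross** (256×256): plus shape, arm width side/4, arm length 3·side/4 —
  four concave corners; drawn by pixel-center rectangle membership so the
  truth mask is exact.
* **noisy_circle** (300×300): disk of radius side/4 with additive Gaussian
  noise, mean 0 and variance 0.04 on the normalized [0, 1] scale, clipped
  back to [0, 1] — the convention of MATLAB's `imnoise`, which this fixture
  family comes from. The default full-contrast (255/0) disk means the
  clipping truncates the interior noise to variance σ²(1/2 − 1/(2π)) ≈
  0.0136; a mid-gray foreground preserves the nominal 0.04 but leaves too
  little edge contrast for *any* hysteresis thresholds to separate edges
  from variance-0.04 noise, so full contrast is the fixture's default.
* **star** (160×160): star polygon, outer radius 0.45·side, inner
  0.18·side, default 5 points — deep concavities.

What the fixtures do **not** emulate: texture, intensity inhomogeneity,
partial-volume blur, neighboring structures with competing edges, or
low-contrast boundaries — all present in clinical CT/MR. Passing the
fixture suite shows the optimizer finds detected edges and handles
concavities and moderate noise; it does not certify clinical accuracy,
which in practice is limited by the quality of the edge map.

## Problem sizes used in the test suite

Quality checks run the full method at the fixtures' native sizes (300²,
256², 160²), 10 seeds each, with the standard operating point (20
iterations, φ = 0.8, κ = 0.5, 15 or 25 snakes, g = 15 or 10). Oracle
equivalence checks (distance transform, Hausdorff, greedy argmin) use
random 20×20–40×40 inputs where exhaustive brute force is exact and cheap.
Mesh combinatorics are exercised on 5- and 18-slice synthetic stacks.

## Known limitations

* One origin, one closed star-shaped-in-angle contour: the output polygon
  has exactly one vertex per angular section, so boundaries that cross a
  ray more than once (deep folded concavities, e.g. the cross corners cut
  at 45°) are approximated by the nearest edge along the ray.
* The method stands or falls with the edge map; an empty or badly broken
  Canny output is reported as an error rather than silently segmented.
* The greedy baseline inherits the shrink bias discussed above; its results
  depend on the sweep budget.
* Mesh reconstruction assumes slice contours share the origin and g (true
  by construction in series mode); no end caps, smoothing or interpolation.
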
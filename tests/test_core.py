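"""Polar layout, swarm mechanics, and full MACPSO segmentation runs."""

import math

import numpy as np
import pytest

from macpso import (
    InvalidInitializationError,
    InvalidOriginError,
    InvalidParameterError,
    NoEdgesError,
    PSOParams,
    build_layout,
    constrain_particle,
    distance_map,
    fitness,
    init_swarms,
    jaccard,
    pso_step,
    run_macpso,
    sections_from_g,
)
from macpso.core import Particle, Swarm
from tests.conftest import random_edge_map


class _ForcedRng:
    """Stand-in RNG whose uniform draws are always 1.0."""

    def random(self):
        return 1.0


class TestSectionsFromG:
    def test_printed_counts(self):
        assert sections_from_g(10) == 63
        assert sections_from_g(15) == 42

    @pytest.mark.parametrize("n", [3, 7, 42, 63, 200])
    def test_inverse_of_conversion(self, n):
        g = 2 * math.pi * 100 / n
        assert sections_from_g(g) == n

    def test_degree_units(self):
        assert sections_from_g(10, "degree") == 36
        assert sections_from_g(15, "degree") == 24

    def test_invalid_g(self):
        with pytest.raises(InvalidParameterError):
            sections_from_g(0)
        with pytest.raises(InvalidParameterError):
            sections_from_g(-3)


class TestBuildLayout:
    def test_quadrant_bounds(self):
        g = 2 * math.pi * 100 / 4
        layout = build_layout((10, 10), g, (21, 21))
        assert layout.n_sections == 4
        assert np.allclose(layout.section_edges, [0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi])

    def test_partition_is_exact(self):
        layout = build_layout((50, 60), 15, (120, 120))
        widths = np.diff(layout.section_edges)
        assert np.isclose(widths.sum(), 2 * np.pi, atol=1e-12)
        assert layout.n_sections == 42

    def test_every_angle_maps_to_one_section(self):
        layout = build_layout((50, 50), 10, (101, 101))
        rng = np.random.default_rng(0)
        for a in rng.uniform(0, 2 * np.pi, 10_000):
            idx = layout.section_of(a)
            assert layout.section_edges[idx] <= a < layout.section_edges[idx + 1]

    def test_origin_outside_rejected(self):
        with pytest.raises(InvalidOriginError):
            build_layout((150, 10), 15, (100, 100))


def _tiny_setup(seed=0, side=40, g=2 * math.pi * 100 / 8, n_snakes=3):
    rng = np.random.default_rng(seed)
    edges = random_edge_map(rng, side, 15)
    dmap = distance_map(edges)
    layout = build_layout(((side - 1) / 2, (side - 1) / 2), g, dmap.shape)
    params = PSOParams(g=g, n_snakes=n_snakes, iterations=5, seed=seed)
    return layout, params, dmap


class TestInitSwarms:
    def test_singleton_swarm_gbest_is_its_particle(self):
        layout, params, dmap = _tiny_setup(n_snakes=1)
        params = PSOParams(**{**params.__dict__, "n_snakes": 1})
        swarms = init_swarms(layout, params, dmap)
        for s in swarms:
            assert s.gbest_r == s.particles[0].r
            assert s.gbest_fitness == s.particles[0].pbest_fitness

    def test_total_particle_count_25_snakes_63_sections(self):
        dmap = distance_map(random_edge_map(np.random.default_rng(1), 80, 30))
        layout = build_layout((39.5, 39.5), 10, dmap.shape)
        params = PSOParams(g=10, n_snakes=25)
        swarms = init_swarms(layout, params, dmap)
        assert layout.n_sections == 63
        assert sum(len(s.particles) for s in swarms) == 1575

    def test_defaults_match_standard_operating_point(self):
        p = PSOParams()
        assert (p.iterations, p.inertia, p.learning_factor, p.n_snakes) == (20, 0.8, 0.5, 15)

    def test_explicit_radii_leaving_image_rejected(self):
        layout, params, dmap = _tiny_setup()
        bad = PSOParams(**{**params.__dict__, "init_radii": [5.0, 10.0, 500.0]})
        with pytest.raises(InvalidInitializationError):
            init_swarms(layout, bad, dmap)

    def test_initial_pbest_equals_position_and_velocity_zero(self):
        layout, params, dmap = _tiny_setup()
        for s in init_swarms(layout, params, dmap):
            for p in s.particles:
                assert p.v == 0.0
                assert p.pbest_r == p.r
                assert p.pbest_fitness == p.fitness


class TestFitness:
    def test_zero_on_edge_pixel_and_ray_distance(self):
        edges = np.zeros((41, 41), dtype=np.uint8)
        layout = build_layout((20, 20), 2 * math.pi * 100 / 8, (41, 41))
        a = layout.section_center_angle[0]
        ex = int(round(20 + 5 * math.cos(a)))
        ey = int(round(20 + 5 * math.sin(a)))
        edges[ey, ex] = 1
        dmap = distance_map(edges)
        r_edge = math.hypot(ex - 20, ey - 20)
        assert fitness(dmap, layout, 0, r_edge) <= 0.71
        assert fitness(dmap, layout, 0, 0.0) == pytest.approx(math.hypot(ex - 20, ey - 20))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_within_interpolation_bound(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_edge_map(rng, 32, 10)
        dmap = distance_map(edges)
        layout = build_layout((15.5, 15.5), 15, (32, 32))
        er, ec = np.nonzero(edges)
        for _ in range(30):
            s = int(rng.integers(0, layout.n_sections))
            r = float(rng.uniform(0, layout.r_max[s]))
            x, y = layout.position(s, r)
            brute = np.sqrt(((ec - x) ** 2 + (er - y) ** 2)).min()
            assert abs(fitness(dmap, layout, s, r) - brute) <= 0.71

    def test_out_of_bounds_is_worst(self):
        layout, _, dmap = _tiny_setup()
        assert fitness(dmap, layout, 0, -1.0) == math.inf
        assert fitness(dmap, layout, 0, 1e6) == math.inf


class TestPsoStep:
    def test_stationary_at_consensus(self):
        layout, params, dmap = _tiny_setup()
        p = Particle(0, 10.0, v=0.0, pbest_r=10.0, pbest_fitness=1.0)
        swarm = Swarm(0, [p], gbest_r=10.0, gbest_fitness=1.0)
        pso_step(swarm, params, np.random.default_rng(0), dmap, layout)
        assert p.r == 10.0 and p.v == 0.0

    def test_pure_inertia(self):
        layout, _, dmap = _tiny_setup()
        params = PSOParams(inertia=1.0, learning_factor=0.0, n_snakes=1, g=2 * math.pi * 100 / 8)
        p = Particle(0, 10.0, v=2.0, pbest_r=10.0, pbest_fitness=1.0)
        swarm = Swarm(0, [p], gbest_r=10.0, gbest_fitness=1.0)
        pso_step(swarm, params, np.random.default_rng(0), dmap, layout)
        assert p.v == pytest.approx(2.0)
        assert p.r == pytest.approx(12.0)

    def test_hand_computed_update_with_forced_uniforms(self):
        # v = 0.8*1 + 0.5*1*(12-10) + 0.5*1*(16-10) = 4.8 ; r = 14.8
        dmap = distance_map(random_edge_map(np.random.default_rng(0), 80, 20))
        layout = build_layout((39.5, 39.5), 2 * math.pi * 100 / 8, dmap.shape)
        params = PSOParams(inertia=0.8, learning_factor=0.5, n_snakes=1, g=2 * math.pi * 100 / 8)
        p = Particle(0, 10.0, v=1.0, pbest_r=12.0, pbest_fitness=0.5)
        swarm = Swarm(0, [p], gbest_r=16.0, gbest_fitness=0.1)
        pso_step(swarm, params, _ForcedRng(), dmap, layout)
        assert p.v == pytest.approx(4.8, abs=1e-12)
        assert p.r == pytest.approx(14.8, abs=1e-12)

    def test_pbest_dominates_current_fitness(self):
        layout, params, dmap = _tiny_setup(seed=3)
        swarms = init_swarms(layout, params, dmap)
        rng = np.random.default_rng(9)
        for _ in range(5):
            for s in swarms:
                pso_step(s, params, rng, dmap, layout)
                for p in s.particles:
                    assert p.pbest_fitness <= p.fitness + 1e-12
                assert s.gbest_fitness == min(p.pbest_fitness for p in s.particles)


class TestConstrain:
    def test_interior_point_unchanged(self):
        layout, _, _ = _tiny_setup()
        p = Particle(0, 5.0, v=1.0)
        constrain_particle(p, layout)
        assert p.r == 5.0 and p.v == 1.0

    def test_negative_radius_clipped(self):
        layout, _, _ = _tiny_setup()
        p = Particle(0, -3.0, v=-2.0)
        constrain_particle(p, layout)
        assert p.r == 0.0 and p.v == 0.0

    def test_overshoot_clipped_to_ray_box_intersection(self):
        layout, _, _ = _tiny_setup(side=40)
        s = 1
        # independent ray-box oracle
        ox = oy = (40 - 1) / 2
        a = layout.section_center_angle[s]
        dx, dy = math.cos(a), math.sin(a)
        cands = []
        for bound, d, o in [(39, dx, ox), (39, dy, oy)]:
            if d > 1e-12:
                cands.append((bound - o) / d)
            elif d < -1e-12:
                cands.append(-o / d)
        r_max = min(cands)
        p = Particle(s, r_max + 7.2, v=3.0)
        constrain_particle(p, layout)
        assert p.r == pytest.approx(r_max)
        assert p.v == 0.0


class TestRunMacpso:
    def test_disk_every_section_reaches_edge(self, clean_disk):
        res = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(seed=0))
        # every ray crosses the ring, so each section's gbest ends on/near it
        for x, y in res.contour.points:
            r = math.hypot(x - 79.5, y - 79.5)
            assert abs(r - 40) < 6  # near the ring radius
        assert res.fitness_trace[-1] <= 1.0

    def test_trace_non_increasing(self, clean_disk):
        res = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(seed=2))
        trace = np.asarray(res.fitness_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_contour_has_42_points_when_g_is_15(self, clean_disk):
        res = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(g=15.0, seed=1))
        assert len(res.contour) == 42
        assert len(res.fitness_trace) == res.iterations_run

    def test_seed_determinism(self, clean_disk):
        a = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(seed=11))
        b = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(seed=11))
        assert np.array_equal(a.contour.points, b.contour.points)
        assert a.fitness_trace == b.fitness_trace
        assert np.array_equal(a.mask, b.mask)

    def test_uniform_image_raises_no_edges(self):
        with pytest.raises(NoEdgesError):
            run_macpso(np.full((64, 64), 0.5), origin=(32, 32))

    def test_origin_outside_rejected(self, clean_disk):
        with pytest.raises(InvalidOriginError):
            run_macpso(clean_disk.image, origin=(500, 500))

    def test_convex_shape_recovery_ten_seeds(self, clean_disk):
        js = []
        for seed in range(10):
            res = run_macpso(clean_disk.image, origin=(79.5, 79.5), params=PSOParams(seed=seed))
            js.append(jaccard(res.mask, clean_disk.truth_mask))
        assert min(js) >= 0.95

    def test_auto_origin_lands_inside_disk(self, clean_disk):
        res = run_macpso(clean_disk.image, params=PSOParams(seed=0))
        ox, oy = res.params_used["origin"]
        assert math.hypot(ox - 79.5, oy - 79.5) < 5
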
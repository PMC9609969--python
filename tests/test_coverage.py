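"""Scene generation and circular-vs-rectangular capture comparison."""

import json
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from circam import (
    CameraPose,
    CircularDomain,
    DegenerateGeometryError,
    DomainError,
    FoodItem,
    PackingError,
    RectangularDomain,
    SceneParams,
    SceneSpec,
    back_project,
    classify_capture,
    compare_domains,
    generate_scene,
    monte_carlo_coverage,
    optimal_pitch,
    project_item,
    uniform_disk,
)
from circam.coverage import camera_rotation

FOVS = (60.0, 100.0, 140.0, 180.0)


class TestSceneGeneration:
    def test_same_seed_same_scene_bytewise(self):
        a = generate_scene(SceneParams(), 42).to_json()
        b = generate_scene(SceneParams(), 42).to_json()
        assert a == b

    def test_different_seeds_differ(self):
        assert generate_scene(SceneParams(), 1).to_json() != generate_scene(
            SceneParams(), 2
        ).to_json()

    def test_items_do_not_overlap(self):
        for seed in range(20):
            scene = generate_scene(SceneParams(), seed)
            for i, a in enumerate(scene.items):
                for b in scene.items[i + 1:]:
                    d = math.hypot(a.center[0] - b.center[0],
                                   a.center[1] - b.center[1])
                    assert d > a.radius + b.radius

    def test_zero_items_vacuous_coverage(self, fisheye):
        params = SceneParams(n_items=(0, 0))
        scene = generate_scene(params, 3)
        assert scene.items == ()
        rep = compare_domains(scene, fisheye, FOVS)
        assert all(e.loss == 0.0 for e in rep.entries)

    def test_infeasible_packing_raises(self):
        params = SceneParams(n_items=(40, 40), item_radius=(0.2, 0.2),
                             scene_disk_radius=0.3, max_attempts=200)
        with pytest.raises(PackingError):
            generate_scene(params, 0)

    def test_uniform_disk_chi_square(self):
        """10^4 draws pass a uniformity test over equal-area sectors."""
        rng = np.random.default_rng(7)
        pts = uniform_disk(rng, 10_000, 1.0)
        r = np.hypot(pts[:, 0], pts[:, 1])
        phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
        r_bin = np.digitize(r**2, np.linspace(0, 1, 6)[1:-1])
        a_bin = np.digitize(phi, np.linspace(0, 2 * np.pi, 9)[1:-1])
        counts = np.bincount(r_bin * 8 + a_bin, minlength=40)
        assert chisquare(counts).pvalue > 0.01

    def test_camera_below_table_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            SceneSpec(table_z=0.0, items=(),
                      camera=CameraPose(position=(0, 0, -0.1)))


class TestProjection:
    def test_on_axis_item_lands_at_center(self, fisheye):
        """With the aiming pitch, a centred item projects around the origin."""
        h, d = 0.4, 0.5
        pose = CameraPose(position=(0, 0, h), pitch_deg=optimal_pitch(h, d))
        item = FoodItem(center=(0.0, d), radius=0.01)
        uv, visible = project_item(fisheye, pose, item)
        assert visible.all()
        # the centre ray itself maps exactly to the image centre
        rot = camera_rotation(pose)
        centre_cam = (np.array([0.0, d, 0.0]) - np.array([0, 0, h])) @ rot
        from circam import project_direction

        assert project_direction(fisheye, centre_cam) == pytest.approx(
            (0.0, 0.0), abs=1e-9
        )
        # boundary samples ring the centre; mean offset is only the tiny
        # foreshortening of the tilted table disk
        assert np.abs(uv.mean(axis=0)).max() < 0.1
        assert np.hypot(uv[:, 0], uv[:, 1]).max() < 15.0

    def test_horizontal_lens_puts_table_item_far_off_axis(self, fisheye):
        """Pitch 0: an item below the camera sits ~atan(h/d) off axis."""
        h, d = 0.4, 0.4
        pose = CameraPose(position=(0, 0, h), pitch_deg=0.0)
        item = FoodItem(center=(0.0, d), radius=0.005)
        uv, visible = project_item(fisheye, pose, item)
        assert visible.all()
        angles = [
            math.degrees(math.acos(back_project(fisheye, p)[2])) for p in uv
        ]
        assert np.mean(angles) == pytest.approx(45.0, abs=1.5)

    def test_projection_consistent_with_back_projection(self, fisheye):
        scene = generate_scene(SceneParams(), 11)
        rot = camera_rotation(scene.camera)
        for item in scene.items:
            uv, visible = project_item(
                fisheye, scene.camera, item, table_z=scene.table_z
            )
            world = item.boundary_points(scene.table_z, 64)
            cam = (world - np.asarray(scene.camera.position)) @ rot
            for p, c, vis in zip(uv, cam, visible):
                if vis:
                    d = back_project(fisheye, p)
                    np.testing.assert_allclose(
                        d, c / np.linalg.norm(c), atol=1e-8
                    )

    def test_degenerate_camera_height(self, fisheye):
        pose = CameraPose(position=(0, 0, 0.0))
        with pytest.raises(DegenerateGeometryError):
            project_item(fisheye, pose, FoodItem((0, 0.3), 0.05), table_z=0.0)

    def test_too_few_boundary_samples(self, fisheye):
        pose = CameraPose(position=(0, 0, 0.4), pitch_deg=45)
        with pytest.raises(DomainError):
            project_item(fisheye, pose, FoodItem((0, 0.4), 0.05), n_boundary=4)


class TestClassification:
    def test_all_points_at_center_full(self):
        uv = np.zeros((8, 2))
        vis = np.ones(8, bool)
        assert classify_capture(uv, vis, CircularDomain((0, 0), 5)) == "full"
        assert classify_capture(
            uv, vis, RectangularDomain((0, 0), 4, 3)
        ) == "full"

    def test_zero_radius_domain_missed(self):
        uv = np.ones((8, 2))
        vis = np.ones(8, bool)
        assert classify_capture(uv, vis, CircularDomain((0, 0), 0)) == "missed"

    def test_partial_inside_is_cut(self):
        uv = np.array([[0.0, 0.0], [10.0, 0.0]])
        vis = np.ones(2, bool)
        assert classify_capture(uv, vis, CircularDomain((0, 0), 5)) == "cut"

    def test_invisible_samples_prevent_full(self):
        uv = np.array([[0.0, 0.0], [np.nan, np.nan]])
        vis = np.array([True, False])
        assert classify_capture(uv, vis, CircularDomain((0, 0), 5)) == "cut"

    def test_rect_full_implies_circumscribing_circle_full(self, fisheye, rng):
        rect = RectangularDomain((0, 0), 8, 6)
        circle = CircularDomain((0, 0), 5)  # circumscribes the 8x6 rectangle
        for _ in range(50):
            uv = rng.uniform(-6, 6, (16, 2))
            vis = np.ones(16, bool)
            if classify_capture(uv, vis, rect) == "full":
                assert classify_capture(uv, vis, circle) == "full"


class TestCoverageComparison:
    def test_domains_nested_rect_inside_circle(self):
        circle = CircularDomain((0, 0), 10)
        rect = RectangularDomain.inscribed_in(circle, 4 / 3)
        assert rect.width == pytest.approx(16.0)
        assert rect.height == pytest.approx(12.0)
        corners = np.array(
            [[rect.width / 2, rect.height / 2], [-rect.width / 2, rect.height / 2]]
        )
        assert circle.contains(corners).all()

    def test_dominance_and_monotonicity_single_scenes(self, fisheye):
        for seed in range(30):
            scene = generate_scene(SceneParams(), seed)
            rep = compare_domains(scene, fisheye, FOVS)
            circ = [rep.entry(f, "circular").loss for f in FOVS]
            rect = [rep.entry(f, "rectangular").loss for f in FOVS]
            assert all(r >= c for r, c in zip(rect, circ))
            assert all(b <= a + 1e-12 for a, b in zip(circ, circ[1:]))

    def test_counts_sum_to_items(self, fisheye):
        scene = generate_scene(SceneParams(), 5)
        rep = compare_domains(scene, fisheye, FOVS)
        for e in rep.entries:
            assert e.n_full + e.n_cut + e.n_missed == len(scene.items)

    def test_hemisphere_domain_misses_nothing_in_front(self, fisheye):
        """A 180-degree circular domain cannot *miss* an item ahead of the lens."""
        for seed in range(20):
            scene = generate_scene(SceneParams(tilt_jitter_deg=0.0), seed)
            rep = compare_domains(scene, fisheye, [180.0])
            assert rep.entry(180.0, "circular").n_missed == 0

    def test_single_draw_equals_compare_domains(self, fisheye):
        params = SceneParams()
        mc = monte_carlo_coverage(params, fisheye, FOVS, n_draws=1, seed=9)
        single = compare_domains(generate_scene(params, 9), fisheye, FOVS)
        for f in FOVS:
            for kind in ("circular", "rectangular"):
                assert mc.entry(f, kind).mean_loss == pytest.approx(
                    single.entry(f, kind).loss
                )

    def test_monte_carlo_reproducible_bytewise(self, fisheye):
        a = monte_carlo_coverage(SceneParams(), fisheye, (100.0,), n_draws=5,
                                 seed=3).to_json()
        b = monte_carlo_coverage(SceneParams(), fisheye, (100.0,), n_draws=5,
                                 seed=3).to_json()
        assert a == b
        json.loads(a)  # valid JSON

    def test_mean_dominance(self, fisheye):
        rep = monte_carlo_coverage(SceneParams(), fisheye, FOVS, n_draws=40,
                                   seed=17)
        for f in FOVS:
            assert rep.entry(f, "rectangular").mean_loss >= rep.entry(
                f, "circular"
            ).mean_loss

    def test_ci_width_shrinks_like_sqrt_n(self, fisheye):
        small = monte_carlo_coverage(SceneParams(), fisheye, (100.0,),
                                     n_draws=100, seed=1)
        large = monte_carlo_coverage(SceneParams(), fisheye, (100.0,),
                                     n_draws=400, seed=1)
        w_small = small.entry(100.0, "rectangular").ci95_halfwidth
        w_large = large.entry(100.0, "rectangular").ci95_halfwidth
        assert w_small / w_large == pytest.approx(2.0, abs=0.5)


class TestOptimalPitch:
    def test_equal_height_distance_is_45(self):
        assert optimal_pitch(0.4, 0.4) == pytest.approx(45.0)

    def test_shallow_limit(self):
        assert optimal_pitch(1e-9, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            optimal_pitch(0.0, 0.4)
        with pytest.raises(DomainError):
            optimal_pitch(0.4, -0.1)

    def test_minimises_loss_on_symmetric_scene(self, fisheye):
        """On a one-item scene, loss over a 1-degree pitch grid bottoms out
        at the aiming angle (ties allowed)."""
        h, d = 0.4, 0.4
        item = FoodItem(center=(0.0, d), radius=0.05)
        best = optimal_pitch(h, d)
        losses = {}
        for pitch in range(0, 91):
            pose = CameraPose(position=(0, 0, h), pitch_deg=float(pitch))
            scene = SceneSpec(table_z=0.0, items=(item,), camera=pose)
            rep = compare_domains(scene, fisheye, [40.0])
            losses[pitch] = rep.entry(40.0, "circular").loss
        pose = CameraPose(position=(0, 0, h), pitch_deg=best)
        scene = SceneSpec(table_z=0.0, items=(item,), camera=pose)
        loss_at_best = compare_domains(scene, fisheye, [40.0]).entry(
            40.0, "circular"
        ).loss
        assert loss_at_best <= min(losses.values())
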
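"""Exact ray tracing: Snell/reflection laws, chief-ray search, the paraxial
oracle, pupil projection, and the full observation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from purkinjeye.eye_model import EyeGeometry, GazeTarget, SurfaceSpec, build_eye, rotate_eye
from purkinjeye.raytrace import (
    Ray,
    TraceError,
    _paraxial_image,
    intersect_surface,
    paraxial_purkinje,
    project_pupil,
    purkinje_path,
    refract,
    reflect,
    simulate_observation,
    trace_path,
    trace_purkinje,
)
from purkinjeye.scene import SceneConfig


def _surface(radius, vertex_z=0.0, n1=1.0, n2=1.336, conic=0.0, aperture=5.0):
    return SurfaceSpec("s", vertex_z, radius, conic, n1, n2, aperture)


class TestRefract:
    def test_equal_indices_leave_direction_unchanged(self):
        s = _surface(7.72, n2=1.0)
        ray = Ray(np.array([0.5, 0.2, 10.0]), np.array([0.0, 0.0, -1.0]))
        out = refract(ray, s)
        assert np.allclose(out.direction, ray.direction, atol=1e-12)

    def test_normal_incidence_unchanged(self):
        s = _surface(7.72)
        ray = Ray(np.array([0.0, 0.0, 10.0]), np.array([0.0, 0.0, -1.0]))
        out = refract(ray, s)
        assert np.allclose(out.direction, [0.0, 0.0, -1.0], atol=1e-12)

    def test_scalar_snell_at_30_degrees(self):
        # plane interface air -> aqueous: arcsin(sin 30 / 1.336) = 21.97 deg
        s = _surface(math.inf, n2=1.336)
        d = np.array([math.sin(math.radians(30)), 0.0, -math.cos(math.radians(30))])
        out = refract(Ray(np.array([-5.0, 0.0, 8.0]), d), s)
        angle = math.degrees(math.asin(abs(out.direction[0])))
        assert angle == pytest.approx(math.degrees(math.asin(math.sin(math.radians(30)) / 1.336)), abs=1e-9)

    def test_total_internal_reflection_raises(self):
        s = _surface(math.inf, n1=1.0, n2=1.336)
        # leaving the dense medium beyond the critical angle (~48.4 deg)
        d = np.array([math.sin(math.radians(60)), 0.0, math.cos(math.radians(60))])
        ray = Ray(np.array([-3.0, 0.0, -2.0]), d)
        with pytest.raises(TraceError, match="total internal reflection"):
            refract(ray, s)

    def test_snell_invariant_random_rays(self, rng):
        """n sin(theta) is conserved to 1e-10 for random oblique rays."""
        s = _surface(7.72, n2=1.376)
        for _ in range(500):
            target = np.array([rng.uniform(-3, 3), rng.uniform(-3, 3), 0.0])
            origin = np.array([rng.uniform(-20, 20), rng.uniform(-20, 20), 60.0])
            ray = Ray(origin, target - origin)
            try:
                p, n = intersect_surface(ray, s)
                out = refract(ray, s)
            except TraceError:
                continue
            sin_i = np.linalg.norm(np.cross(ray.direction, n))
            sin_t = np.linalg.norm(np.cross(out.direction, n))
            assert abs(1.0 * sin_i - 1.376 * sin_t) < 1e-10


class TestReflect:
    def test_normal_incidence_reversed(self):
        s = _surface(7.72)
        out = reflect(Ray(np.array([0.0, 0.0, 10.0]), np.array([0.0, 0.0, -1.0])), s)
        assert np.allclose(out.direction, [0.0, 0.0, 1.0], atol=1e-12)

    def test_planar_mirror_image_direction(self):
        s = _surface(math.inf)
        d = np.array([0.3, 0.1, -0.9])
        out = reflect(Ray(np.array([0.0, 0.0, 5.0]), d), s)
        expect = d / np.linalg.norm(d) * np.array([1, 1, -1])
        assert np.allclose(out.direction, expect, atol=1e-12)

    def test_reflection_law_and_coplanarity(self, rng):
        s = _surface(6.5, vertex_z=-0.55)
        for _ in range(500):
            target = np.array([rng.uniform(-3, 3), rng.uniform(-3, 3), -0.6])
            origin = np.array([rng.uniform(-30, 30), rng.uniform(-30, 30), 70.0])
            ray = Ray(origin, target - origin)
            try:
                p, n = intersect_surface(ray, s)
                out = reflect(ray, s)
            except TraceError:
                continue
            cos_i = abs(float(ray.direction @ n))
            cos_r = abs(float(out.direction @ n))
            assert abs(cos_i - cos_r) < 1e-10
            # reflected ray lies in the plane of incidence
            assert abs(float(np.cross(ray.direction, n) @ out.direction)) < 1e-10


class TestChiefRay:
    def test_symmetric_scene_puts_p1_on_symmetry_line(self):
        scene = SceneConfig(
            led_position=[10.0, 0.0, 70.0],
            camera_pinhole=[-10.0, 0.0, 70.0],
            camera_axis=[10.0, 0.0, -70.0],
            focal_length_px=2000.0,
            sensor_size=(800, 600),
        )
        x, y, vis = trace_purkinje(build_eye(1.0), scene, 1)
        # LED and camera mirror about the x=0 plane; chief ray stays in y=0,
        # so P1 lands on the sensor's horizontal midline
        assert vis
        assert y == pytest.approx(scene.principal_point[1], abs=1e-6)

    def test_p2_forms_within_2px_of_p1(self, scene):
        eye = build_eye(2.0)
        p1 = trace_purkinje(eye, scene, 1)
        p2 = trace_purkinje(eye, scene, 2)
        assert math.hypot(p2[0] - p1[0], p2[1] - p1[1]) < 2.0

    def test_p3_accommodates_more_than_p1(self, scene):
        e1, e4 = build_eye(1.0), build_eye(4.0)
        moves = {}
        for k in (1, 3):
            a = trace_purkinje(e1, scene, k)
            b = trace_purkinje(e4, scene, k)
            moves[k] = math.hypot(b[0] - a[0], b[1] - a[1])
        assert moves[3] > moves[1]

    def test_reversibility_reproduces_led(self, scene):
        from purkinjeye.raytrace import _find_chief_ray, _led_in_eye, _pinhole_in_eye

        eye = rotate_eye(build_eye(2.5), 3.0)
        for k in (1, 3, 4):
            path = purkinje_path(k)
            launch, exit_ray, _ = _find_chief_ray(eye, scene, path)
            back = Ray(_pinhole_in_eye(eye, scene), -exit_ray.direction)
            back_out, _ = trace_path(back, eye, list(reversed(path)), check_aperture=False)
            led = _led_in_eye(eye, scene)
            w = led - back_out.origin
            miss = w - (w @ back_out.direction) * back_out.direction
            assert np.linalg.norm(miss) < 1e-6

    def test_determinism(self, scene):
        t = GazeTarget(0.5, 0.02)
        a = simulate_observation(2.0, t, scene)
        b = simulate_observation(2.0, t, scene)
        assert a == b

    def test_rotation_moves_p4_much_more_than_p1(self, scene):
        eye0 = build_eye(2.5)
        eye5 = rotate_eye(eye0, 5.0)
        d = {}
        for k in (1, 4):
            a = trace_purkinje(eye0, scene, k)
            b = trace_purkinje(eye5, scene, k)
            d[k] = math.hypot(b[0] - a[0], b[1] - a[1])
        assert d[4] > 2.0 * d[1]

    def test_accommodation_feature_monotone(self, scene):
        feats = []
        for a in np.arange(1.0, 4.01, 0.5):
            eye = build_eye(a)
            p3 = trace_purkinje(eye, scene, 3)
            p4 = trace_purkinje(eye, scene, 4)
            feats.append(p4[1] - p3[1])
        diffs = np.diff(feats)
        assert np.all(diffs > 0) or np.all(diffs < 0)


class TestParaxialOracle:
    def _mirror_eye(self, radius):
        surf = [
            SurfaceSpec("m", 0.0, radius, 0.0, 1.0, 1.0, 3.0),
            SurfaceSpec("a", -1.0, 100.0, 0.0, 1.0, 1.0, 3.0),
            SurfaceSpec("b", -2.0, 100.0, 0.0, 1.0, 1.0, 3.0),
            SurfaceSpec("c", -3.0, 100.0, 0.0, 1.0, 1.0, 3.0),
        ]
        return EyeGeometry(
            surfaces=tuple(surf), pupil_z=-1.0, pupil_radius=2.0, axial_length=24.0
        )

    def test_planar_mirror_images_at_symmetric_point(self):
        eye = self._mirror_eye(math.inf)
        z_img, mag = _paraxial_image(eye, 1, s_axial=100.0, h=2.0)
        assert z_img == pytest.approx(-100.0, abs=1e-9)
        assert mag == pytest.approx(1.0, abs=1e-9)

    def test_curved_mirror_equation(self):
        # R=+8 is convex toward the incoming light: virtual image at
        # R s / (2 s + R) behind the mirror, magnification R / (2 s + R)
        R, s = 8.0, 100.0
        eye = self._mirror_eye(R)
        z_img, mag = _paraxial_image(eye, 1, s_axial=s, h=1.0)
        assert z_img == pytest.approx(-R * s / (2 * s + R), rel=1e-9)
        assert mag == pytest.approx(R / (2 * s + R), rel=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("a", [1.0, 4.0])
    def test_exact_agrees_with_paraxial_in_small_angle_limit(
        self, small_angle_scene, k, a
    ):
        eye = build_eye(a)
        ex = trace_purkinje(eye, small_angle_scene, k)
        pa = paraxial_purkinje(eye, small_angle_scene, k)
        assert math.hypot(ex[0] - pa[0], ex[1] - pa[1]) < 0.5


class TestPupilProjection:
    def test_on_axis_camera_sees_circle(self):
        scene = SceneConfig(
            led_position=[10.0, 0.0, 70.0],
            camera_pinhole=[0.0, 0.0, 70.0],
            camera_axis=[0.0, 0.0, -1.0],
            focal_length_px=1800.0,
            sensor_size=(400, 300),
        )
        obs = project_pupil(build_eye(2.0), scene)
        assert obs.r2 / obs.r1 > 0.99

    def test_rotation_foreshortens_pupil(self, scene):
        base = project_pupil(build_eye(2.0), scene)
        rot = project_pupil(rotate_eye(build_eye(2.0), 7.0), scene)
        assert rot.r2 / rot.r1 < base.r2 / base.r1

    def test_axes_scale_linearly_with_pupil_radius(self, scene, eye_params):
        small = project_pupil(build_eye(2.0, eye_params.perturbed(pupil_radius=1.25)), scene)
        big = project_pupil(build_eye(2.0, eye_params.perturbed(pupil_radius=2.5)), scene)
        assert big.r1 / small.r1 == pytest.approx(2.0, rel=0.02)
        assert big.r2 / small.r2 == pytest.approx(2.0, rel=0.02)


class TestObservation:
    def test_full_observation_visible_at_default_conditions(self, scene):
        pset, pupil = simulate_observation(2.5, GazeTarget(0.4, 0.0315 * 0.4), scene)
        assert pset.vis_P1 and pset.vis_P3 and pset.vis_P4
        assert pupil.r1 >= pupil.r2 > 0

    def test_out_of_range_purkinje_index(self):
        with pytest.raises(Exception):
            purkinje_path(5)
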
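"""Purkinje-image formation by exact ray tracing, with a paraxial oracle.

Purkinje images P1-P4 are reflections of the illumination LED from the four
optical surfaces of the eye: anterior cornea (P1), posterior cornea (P2),
anterior lens (P3) and posterior lens (P4).  For surface k the chief ray is
the single ray from the LED that refracts through surfaces 1..k-1, reflects
at surface k, refracts back out through k-1..1, and passes exactly through
the camera pinhole.  It is found by a damped two-parameter root search over
the launch direction; the sensor position is the pinhole projection of the
exiting ray.

``paraxial_purkinje`` provides an independent closed-form check: the LED's
virtual image under sequential paraxial refraction, paraxial mirror imaging
at surface k and paraxial refraction back out, projected through the same
pinhole.  Exact and paraxial positions agree in the small-angle limit.

All exact tracing happens in the eye's own frame (apex at origin, optical
axis along -z); rays are transformed in and out through the eye's rigid
pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .eye_model import (
    AccommodationState,
    EyeGeometry,
    EyeParameters,
    GazeTarget,
    ParameterError,
    SurfaceSpec,
    build_eye,
    rotate_eye,
    rotation_angle,
)
from .scene import SceneConfig

__all__ = [
    "Ray",
    "PurkinjeSet",
    "PupilObservation",
    "TraceError",
    "refract",
    "reflect",
    "intersect_surface",
    "trace_path",
    "purkinje_path",
    "trace_purkinje",
    "paraxial_purkinje",
    "project_pupil",
    "simulate_observation",
]

_EZ = np.array([0.0, 0.0, 1.0])


class TraceError(RuntimeError):
    """A ray missed a surface, hit total internal reflection, or the chief-ray
    search failed to converge."""


@dataclass(frozen=True)
class Ray:
    """A ray in the eye frame: origin [mm] and unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ParameterError("ray direction must be a nonzero finite vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class PurkinjeSet:
    """Sensor-plane Purkinje spot positions [px] with visibility flags.

    P2 is computed but, being formed within ~2 px of P1, is merged into P1
    downstream; it is carried here for completeness.
    """

    x_P1: float
    y_P1: float
    x_P3: float
    y_P3: float
    x_P4: float
    y_P4: float
    vis_P1: bool = True
    vis_P3: bool = True
    vis_P4: bool = True
    x_P2: float | None = None
    y_P2: float | None = None
    vis_P2: bool = False

    def spot(self, name: str) -> tuple[float, float, bool]:
        return (
            getattr(self, f"x_{name}"),
            getattr(self, f"y_{name}"),
            getattr(self, f"vis_{name}"),
        )


@dataclass(frozen=True)
class PupilObservation:
    """Projected entrance-pupil ellipse: center and semi-axes [px], r1 >= r2."""

    x_PC: float
    y_PC: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.r1 >= self.r2 > 0):
            raise ParameterError("pupil semi-axes must satisfy r1 >= r2 > 0")


# ---------------------------------------------------------------------------
# Surface intersection and Snell's law


def _conic_coeffs(surface: SurfaceSpec, w: np.ndarray, d: np.ndarray):
    """Quadratic coefficients of F(o + t d) for the conicoid
    rho^2 + (1+Q) zeta^2 - 2 R zeta = 0 with zeta measured from the vertex
    toward the retina (local axis a = -z)."""
    q = surface.conic
    wz, dz = -w[2], -d[2]  # zeta components (axis points toward retina)
    a2 = float(d @ d) + q * dz * dz
    a1 = 2.0 * (float(w @ d) + q * wz * dz - surface.radius * dz)
    a0 = float(w @ w) + q * wz * wz - 2.0 * surface.radius * wz
    return a2, a1, a0


def intersect_surface(
    ray: Ray, surface: SurfaceSpec, check_aperture: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect ``ray`` with ``surface`` (eye frame).

    Returns ``(point, outward_normal)`` where the normal is the unit surface
    normal pointing toward the scene (+z side).  Raises :class:`TraceError`
    on a miss.  ``check_aperture=False`` intersects the unbounded surface
    (used while the chief-ray search explores off-aperture launch angles).
    """
    vertex = np.array([0.0, 0.0, surface.vertex_z])
    o, d = ray.origin, ray.direction
    if surface.is_planar:
        if abs(d[2]) < 1e-15:
            raise TraceError(f"{surface.name}: ray parallel to planar surface")
        t = (surface.vertex_z - o[2]) / d[2]
        if t <= 1e-9:
            raise TraceError(f"{surface.name}: planar surface behind ray")
        p = ray.at(t)
        normal = _EZ.copy()
    else:
        w = o - vertex
        a2, a1, a0 = _conic_coeffs(surface, w, d)
        if abs(a2) < 1e-15:
            roots = [-a0 / a1] if abs(a1) > 1e-15 else []
        else:
            disc = a1 * a1 - 4.0 * a2 * a0
            if disc < 0:
                raise TraceError(f"{surface.name}: no intersection")
            sq = math.sqrt(disc)
            roots = [(-a1 - sq) / (2 * a2), (-a1 + sq) / (2 * a2)]
        best = None
        for t in roots:
            if t <= 1e-9:
                continue
            p = ray.at(t)
            zeta = -(p[2] - surface.vertex_z)
            # keep the vertex-adjacent cap: sag on the centre-of-curvature
            # side, bounded by |R| (rejects the far branch of hyperboloids)
            if surface.radius * zeta < -1e-12 or abs(zeta) > abs(surface.radius):
                continue
            if best is None or t < best:
                best = t
        if best is None:
            raise TraceError(f"{surface.name}: no valid intersection branch")
        p = ray.at(best)
        g = p - vertex + (surface.conic * (-(p[2] - surface.vertex_z)) - surface.radius) * np.array(
            [0.0, 0.0, -1.0]
        )
        gn = np.linalg.norm(g)
        if gn == 0:
            raise TraceError(f"{surface.name}: degenerate normal")
        normal = g / gn
        if normal[2] < 0:
            normal = -normal
    if check_aperture:
        rho2 = p[0] ** 2 + p[1] ** 2
        if rho2 > surface.aperture_radius**2:
            raise TraceError(
                f"{surface.name}: intersection outside aperture "
                f"(rho={math.sqrt(rho2):.3f} mm)"
            )
    return p, normal


def refract(ray: Ray, surface: SurfaceSpec, check_aperture: bool = True) -> Ray:
    """Refract ``ray`` at ``surface`` using vector Snell's law.

    The crossing direction decides the index pair: rays moving toward the
    retina pass n_before -> n_after, rays moving back out pass
    n_after -> n_before.  Raises :class:`TraceError` on miss or total
    internal reflection.
    """
    p, n_out = intersect_surface(ray, surface, check_aperture)
    d = ray.direction
    if float(d @ n_out) < 0:  # entering (toward retina)
        nrm, n1, n2 = n_out, surface.n_before, surface.n_after
    else:  # exiting (toward scene)
        nrm, n1, n2 = -n_out, surface.n_after, surface.n_before
    cos_i = -float(d @ nrm)
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if k < 0:
        raise TraceError(f"{surface.name}: total internal reflection")
    d_new = eta * d + (eta * cos_i - math.sqrt(k)) * nrm
    return Ray(p, d_new)


def reflect(ray: Ray, surface: SurfaceSpec, check_aperture: bool = True) -> Ray:
    """Specularly reflect ``ray`` at ``surface`` (angle in = angle out)."""
    p, n_out = intersect_surface(ray, surface, check_aperture)
    d = ray.direction
    d_new = d - 2.0 * float(d @ n_out) * n_out
    return Ray(p, d_new)


# ---------------------------------------------------------------------------
# Path tracing


def purkinje_path(k: int) -> list[tuple[int, str]]:
    """Interaction sequence for Purkinje image k (1-based surface index)."""
    if not 1 <= k <= 4:
        raise ParameterError("Purkinje index k must be in 1..4")
    into = [(i, "refract") for i in range(k - 1)]
    return into + [(k - 1, "reflect")] + [(i, "refract") for i in reversed(range(k - 1))]


def trace_path(
    ray: Ray,
    eye: EyeGeometry,
    path: Sequence[tuple[int, str]],
    check_aperture: bool = True,
) -> tuple[Ray, list[np.ndarray]]:
    """Trace ``ray`` (eye frame) through ``path``; returns the exiting ray
    and the list of interaction points."""
    points: list[np.ndarray] = []
    for idx, mode in path:
        surface = eye.surfaces[idx]
        if mode == "refract":
            ray = refract(ray, surface, check_aperture)
        elif mode == "reflect":
            ray = reflect(ray, surface, check_aperture)
        else:
            raise ParameterError(f"unknown interaction mode {mode!r}")
        points.append(ray.origin)
    return ray, points


def _pupil_clear(
    start: np.ndarray, points: Iterable[np.ndarray], end_dir: np.ndarray,
    eye: EyeGeometry,
) -> bool:
    """True if every segment of the traced path crosses the iris plane inside
    the pupil opening (eye frame)."""
    zp = eye.pupil_z
    r2max = eye.pupil_radius**2
    prev = start
    pts = list(points)
    # extend the final segment well past the apex plane
    pts.append(pts[-1] + 100.0 * end_dir if pts else start + 100.0 * end_dir)
    for p in pts:
        dz = p[2] - prev[2]
        if abs(dz) > 1e-12:
            s = (zp - prev[2]) / dz
            if 1e-9 < s < 1 - 1e-9:
                cross = prev + s * (p - prev)
                if cross[0] ** 2 + cross[1] ** 2 > r2max:
                    return False
        prev = p
    return True


# ---------------------------------------------------------------------------
# Chief-ray search


def _led_in_eye(eye: EyeGeometry, scene: SceneConfig) -> np.ndarray:
    return eye.to_eye(scene.led_position)


def _pinhole_in_eye(eye: EyeGeometry, scene: SceneConfig) -> np.ndarray:
    return eye.to_eye(scene.camera_pinhole)


def _miss_at_pinhole(exit_ray: Ray, pinhole: np.ndarray) -> np.ndarray:
    """2-vector of the exiting ray's perpendicular miss at the pinhole [mm]."""
    d = exit_ray.direction
    w = pinhole - exit_ray.origin
    perp = w - float(w @ d) * d
    # orthonormal basis perpendicular to d
    a = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return np.array([float(perp @ e1), float(perp @ e2)])


def _find_chief_ray(
    eye: EyeGeometry,
    scene: SceneConfig,
    path: Sequence[tuple[int, str]],
    tol: float = 1e-9,
) -> tuple[Ray, Ray, list[np.ndarray]]:
    """Find the LED ray that follows ``path`` and passes through the pinhole.

    Returns (launch ray, exit ray, interaction points), all in the eye
    frame.  Root search runs on unbounded surfaces; aperture and pupil
    vignetting are judged afterwards by the caller.
    """
    led = _led_in_eye(eye, scene)
    pin = _pinhole_in_eye(eye, scene)

    def residual(ab: np.ndarray) -> np.ndarray:
        aim = np.array([ab[0], ab[1], 0.0])
        try:
            exit_ray, _ = trace_path(Ray(led, aim - led), eye, path, check_aperture=False)
        except TraceError:
            return np.array([1e6 + ab[0] ** 2, 1e6 + ab[1] ** 2])
        return _miss_at_pinhole(exit_ray, pin)

    starts = [(0.0, 0.0)]
    for r in (0.5, 1.0, 2.0, 3.0):
        starts += [(r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r), (r, r), (-r, -r), (r, -r), (-r, r)]
    last_err = None
    for x0 in starts:
        for method in ("hybr", "lm"):
            sol = optimize.root(residual, np.array(x0), method=method, tol=1e-14)
            if np.linalg.norm(sol.fun) < 1e-6:
                ab = sol.x
                aim = np.array([ab[0], ab[1], 0.0])
                launch = Ray(led, aim - led)
                try:
                    exit_ray, points = trace_path(
                        launch, eye, path, check_aperture=False
                    )
                except TraceError as exc:  # pragma: no cover - converged retrace
                    last_err = exc
                    continue
                if np.linalg.norm(_miss_at_pinhole(exit_ray, pin)) < 1e-6:
                    return launch, exit_ray, points
            last_err = sol
    raise TraceError(f"chief-ray search did not converge: {last_err}")


def trace_purkinje(
    eye: EyeGeometry, scene: SceneConfig, k: int
) -> tuple[float, float, bool]:
    """Sensor position [px] of Purkinje image k and its visibility.

    Visibility is False when the chief ray violates a surface aperture or
    the pupil opening (vignetting), or leaves the sensor bounds.
    """
    path = purkinje_path(k)
    launch, exit_ray, points = _find_chief_ray(eye, scene, path)
    # project: ray arrives at the pinhole travelling along exit direction
    d_scene = eye.direction_to_scene(exit_ray.direction)
    xy = scene.project_incoming(d_scene)

    visible = scene.in_bounds(xy)
    if visible:
        try:
            trace_path(launch, eye, path, check_aperture=True)
        except TraceError:
            visible = False
    if visible and k >= 3:
        visible = _pupil_clear(launch.origin, points, exit_ray.direction, eye)
    return xy[0], xy[1], visible


# ---------------------------------------------------------------------------
# Paraxial oracle


def _paraxial_image(
    eye: EyeGeometry, k: int, s_axial: float, h: float
) -> tuple[float, float]:
    """Paraxial virtual image of a point source for Purkinje k.

    The source sits at axial distance ``s_axial`` [mm] in front of the apex
    with transverse offset ``h``.  Returns (z_image [mm, eye frame],
    transverse magnification).  Uses the reduced-angle formulation with the
    negative-index unfolding of the mirror reflection.
    """
    xi = [-s.vertex_z for s in eye.surfaces]  # axial positions, >= 0 into the eye

    def power(i: int, n1: float, n2: float) -> float:
        return eye.surfaces[i].curvature * (n2 - n1)

    def run(u0: float) -> tuple[float, float]:
        # state at the source plane (xi = -s_axial)
        y, om, n_cur, pos = h, u0, 1.0, -s_axial
        seq_in = [(i, "refract") for i in range(k - 1)] + [(k - 1, "mirror")]
        seq_out = [(i, "refract_back") for i in reversed(range(k - 1))]
        for i, mode in seq_in + seq_out:
            y += om * ((xi[i] - pos) / n_cur)
            pos = xi[i]
            if mode == "refract":
                n_new = eye.surfaces[i].n_after * math.copysign(1.0, n_cur)
            elif mode == "refract_back":
                n_new = eye.surfaces[i].n_before * math.copysign(1.0, n_cur)
            else:  # mirror
                n_new = -n_cur
            om -= y * eye.surfaces[i].curvature * (n_new - n_cur)
            n_cur = n_new
        # exit medium is air travelling back out: propagate to the apex plane
        y += om * ((0.0 - pos) / n_cur)
        return y, om / n_cur  # height at apex, real slope dy/dxi

    du = 1e-4
    y1, m1 = run(-h / s_axial)
    y2, m2 = run(-h / s_axial + du)
    if abs(m1 - m2) < 1e-14:
        raise TraceError("paraxial image at infinity")
    xi_img = (y2 - y1) / (m1 - m2)
    y_img = y1 + m1 * xi_img
    mag = y_img / h if abs(h) > 1e-12 else 1.0
    return -xi_img, mag  # eye-frame z of the image


def paraxial_purkinje(
    eye: EyeGeometry, scene: SceneConfig, k: int
) -> tuple[float, float]:
    """Closed-form small-angle prediction of Purkinje image k [px].

    Images the LED by sequential paraxial refraction into the eye, paraxial
    mirror imaging at surface k and paraxial refraction back out, then
    projects the virtual image through the pinhole.
    """
    led = _led_in_eye(eye, scene)
    if led[2] <= 0:
        raise ParameterError("LED must be on the scene side of the eye")
    hvec = led[:2]
    h = float(np.linalg.norm(hvec))
    z_img, mag = _paraxial_image(eye, k, float(led[2]), h if h > 0 else 1.0)
    if h > 0:
        off = mag * hvec
    else:
        off = np.zeros(2)
    img_eye = np.array([off[0], off[1], z_img])
    img_scene = eye.to_scene(img_eye)
    return scene.project_point(img_scene)


# ---------------------------------------------------------------------------
# Pupil projection


def _newton2d(fun, x0: np.ndarray, tol: float = 1e-9, max_iter: int = 60):
    """Damped 2D Newton with finite-difference Jacobian; None on failure."""
    x = np.asarray(x0, float)
    h = 1e-6
    for _ in range(max_iter):
        f = fun(x)
        if not np.all(np.isfinite(f)) or np.abs(f).max() >= 1e5:
            return None
        if np.linalg.norm(f) < tol:
            return x
        jac = np.empty((2, 2))
        for j in range(2):
            dx = np.zeros(2)
            dx[j] = h
            jac[:, j] = (fun(x + dx) - f) / h
        try:
            step = np.linalg.solve(jac, f)
        except np.linalg.LinAlgError:
            return None
        # backtracking damping
        lam = 1.0
        f0 = np.linalg.norm(f)
        while lam > 1e-4:
            fx = fun(x - lam * step)
            if np.all(np.isfinite(fx)) and np.linalg.norm(fx) < f0:
                x = x - lam * step
                break
            lam *= 0.5
        else:
            return None
    return x if np.linalg.norm(fun(x)) < tol else None


def project_pupil(
    eye: EyeGeometry, scene: SceneConfig, n_rim: int = 24
) -> PupilObservation:
    """Project the pupil rim through the cornea onto the sensor and fit an
    ellipse (entrance-pupil image).

    For each of ``n_rim`` rim points a two-parameter search finds the ray
    from the camera pinhole that, refracted by both corneal surfaces, meets
    that rim point; the launch direction fixes the sensor position.
    """
    if n_rim < 5:
        raise ParameterError("need at least 5 rim points to fit an ellipse")
    pin = _pinhole_in_eye(eye, scene)
    zp = eye.pupil_z
    pts = []
    for phi in np.linspace(0.0, 2.0 * math.pi, n_rim, endpoint=False):
        rim = np.array(
            [eye.pupil_radius * math.cos(phi), eye.pupil_radius * math.sin(phi), zp]
        )

        def residual(ab: np.ndarray) -> np.ndarray:
            aim = np.array([ab[0], ab[1], 0.0])
            ray = Ray(pin, aim - pin)
            try:
                for surf in eye.surfaces[:2]:
                    ray = refract(ray, surf, check_aperture=False)
            except TraceError:
                return np.array([1e6, 1e6])
            if abs(ray.direction[2]) < 1e-12:
                return np.array([1e6, 1e6])
            t = (zp - ray.origin[2]) / ray.direction[2]
            hit = ray.at(t)
            return hit[:2] - rim[:2]

        x = _newton2d(residual, rim[:2].copy())
        if x is None:
            raise TraceError(f"pupil rim point at phi={phi:.2f} is vignetted")
        launch_dir = eye.direction_to_scene(
            Ray(pin, np.array([x[0], x[1], 0.0]) - pin).direction
        )
        # light travels rim -> pinhole along -launch_dir
        pts.append(scene.project_incoming(-launch_dir))
    return _fit_ellipse_px(np.asarray(pts))


def _fit_ellipse_px(points: np.ndarray) -> PupilObservation:
    from skimage.measure import EllipseModel

    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(points)
        if not model:
            raise TraceError("ellipse fit to projected pupil rim failed")
        xc, yc = model.center
        a, b = model.axis_lengths
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(points):
            raise TraceError("ellipse fit to projected pupil rim failed")
        xc, yc, a, b, _ = model.params
    r1, r2 = (a, b) if a >= b else (b, a)
    return PupilObservation(x_PC=float(xc), y_PC=float(yc), r1=float(r1), r2=float(r2))


# ---------------------------------------------------------------------------
# Full observation


def simulate_observation(
    A: AccommodationState | float,
    target: GazeTarget,
    scene: SceneConfig,
    params: EyeParameters | None = None,
    include_p2: bool = True,
) -> tuple[PurkinjeSet, PupilObservation]:
    """Noiseless ground-truth observation for one accommodation/gaze state.

    Builds the eye at ``A``, rotates it by the target-driven angle
    (theta = arctan(d_target/d)) and computes all Purkinje spots plus the
    projected pupil ellipse.
    """
    eye = rotate_eye(build_eye(A, params), rotation_angle(target))
    spots: dict[str, tuple[float, float, bool]] = {}
    for name, k in (("P1", 1), ("P3", 3), ("P4", 4)):
        try:
            spots[name] = trace_purkinje(eye, scene, k)
        except TraceError:
            spots[name] = (math.nan, math.nan, False)
    pset_kwargs: dict = {}
    for name in ("P1", "P3", "P4"):
        x, y, v = spots[name]
        pset_kwargs[f"x_{name}"] = x
        pset_kwargs[f"y_{name}"] = y
        pset_kwargs[f"vis_{name}"] = v
    if include_p2:
        try:
            x2, y2, v2 = trace_purkinje(eye, scene, 2)
            pset_kwargs.update(x_P2=x2, y_P2=y2, vis_P2=v2)
        except TraceError:
            pass
    pupil = project_pupil(eye, scene)
    return PurkinjeSet(**pset_kwargs), pupil
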
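"""Accommodation-dependent, rotatable four-surface schematic eye.

The eye model follows the Navarro accommodation-dependent schematic eye:
four refracting surfaces (anterior/posterior cornea, anterior/posterior
crystalline lens) whose lens radii, lens thickness, anterior-chamber depth
and lens refractive index depend on the accommodation depth ``A`` in
diopters (the reciprocal of the focus distance in meters).  The default
parameter file uses a linear-in-A dependence matched to Navarro's log law
at rest and at 4 D (the log law itself is selectable in the file).  The
axial length from cornea to retina is held constant across accommodation:
the vitreous chamber depth absorbs lens-thickness changes.

Coordinate frame (scene frame): right-handed, origin at the unrotated
corneal apex, ``+z`` pointing from the cornea toward the scene, ``+x``
horizontal (temporal-to-nasal), ``+y`` up.  All geometry is in mm.  Eye
rotation is a rigid rotation in the horizontal (x-z) plane about a center
on the unrotated optical axis, 13.5 mm behind the apex by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SurfaceSpec",
    "EyeGeometry",
    "AccommodationState",
    "GazeTarget",
    "EyeParameters",
    "ParameterError",
    "build_eye",
    "rotation_angle",
    "rotate_eye",
    "load_eye_parameters",
]

_MEDIA = ("cornea", "aqueous", "lens", "vitreous")


class ParameterError(ValueError):
    """Raised when an eye parameter or override violates model invariants."""


@dataclass(frozen=True)
class SurfaceSpec:
    """One refracting/reflecting conicoid surface of the schematic eye.

    ``radius`` is signed: positive means the centre of curvature lies
    toward the retina.  ``math.inf`` flags a planar surface.  ``n_before``
    and ``n_after`` are the refractive indices at the working wavelength on
    the scene side and the retina side of the surface, respectively.
    """

    name: str
    vertex_z: float
    radius: float
    conic: float
    n_before: float
    n_after: float
    aperture_radius: float

    def __post_init__(self) -> None:
        if not self.aperture_radius > 0:
            raise ParameterError(f"{self.name}: aperture_radius must be > 0")
        if not math.isinf(self.radius) and abs(self.radius) <= self.aperture_radius:
            raise ParameterError(
                f"{self.name}: |radius| ({self.radius}) must exceed the "
                f"aperture radius ({self.aperture_radius}) or be planar (inf)"
            )
        for label, n in (("n_before", self.n_before), ("n_after", self.n_after)):
            if not 1.0 <= n <= 1.6:
                raise ParameterError(f"{self.name}: {label}={n} outside [1.0, 1.6]")

    @property
    def is_planar(self) -> bool:
        return math.isinf(self.radius)

    @property
    def curvature(self) -> float:
        return 0.0 if self.is_planar else 1.0 / self.radius


@dataclass(frozen=True)
class AccommodationState:
    """Accommodation depth ``A`` in diopters; A = 1/d for focus distance d [m]."""

    A: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.A <= 10.0:
            raise ParameterError(f"accommodation depth {self.A} D outside [0, 10] D")

    @classmethod
    def from_distance(cls, d_m: float) -> "AccommodationState":
        if d_m <= 0:
            raise ParameterError("focus distance must be > 0 m")
        return cls(1.0 / d_m)

    @property
    def focus_distance_m(self) -> float:
        return math.inf if self.A == 0 else 1.0 / self.A


@dataclass(frozen=True)
class GazeTarget:
    """A fixation target: viewing distance ``d`` [m] and lateral offset
    ``d_target`` [m] of the target from the eye's resting optical axis."""

    d: float
    d_target: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ParameterError("viewing distance d must be > 0")
        if self.d_target < 0:
            raise ParameterError("lateral offset d_target must be >= 0")

    @property
    def accommodation(self) -> AccommodationState:
        return AccommodationState.from_distance(self.d)

    @property
    def position_mm(self) -> np.ndarray:
        """Target point in the scene frame (on-height, horizontal offset)."""
        return np.array([self.d_target * 1e3, 0.0, self.d * 1e3])


def rotation_angle(target: GazeTarget) -> float:
    """Eye rotation angle [deg] required to fixate ``target``.

    theta = arctan(d_target / d); always in [0, 90).
    """
    return math.degrees(math.atan(target.d_target / target.d))


@dataclass(frozen=True)
class EyeGeometry:
    """A posed schematic eye: four ordered surfaces plus pupil and pose.

    Surfaces are stored in the eye's own (unrotated) frame with vertices on
    the -z axis; ``rotation_angle_deg`` and ``rotation_center`` give the
    rigid pose in the scene frame.
    """

    surfaces: tuple[SurfaceSpec, ...]
    pupil_z: float
    pupil_radius: float
    axial_length: float
    rotation_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -13.5])
    )
    rotation_angle_deg: float = 0.0
    accommodation: float = 0.0

    def __post_init__(self) -> None:
        if len(self.surfaces) != 4:
            raise ParameterError("EyeGeometry requires exactly 4 surfaces")
        zs = [s.vertex_z for s in self.surfaces]
        if not all(a > b for a, b in zip(zs, zs[1:])):
            raise ParameterError("surfaces must be strictly ordered along the axis")
        if self.pupil_radius <= 0:
            raise ParameterError("pupil_radius must be > 0")
        object.__setattr__(
            self, "rotation_center", np.asarray(self.rotation_center, dtype=float)
        )

    # -- rigid pose -------------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Scene-from-eye rotation (about +y through rotation_center)."""
        t = math.radians(self.rotation_angle_deg)
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    def to_scene(self, p_eye: np.ndarray) -> np.ndarray:
        return self.rotation_center + self.rotation_matrix @ (
            np.asarray(p_eye, float) - self.rotation_center
        )

    def to_eye(self, p_scene: np.ndarray) -> np.ndarray:
        return self.rotation_center + self.rotation_matrix.T @ (
            np.asarray(p_scene, float) - self.rotation_center
        )

    def direction_to_eye(self, d_scene: np.ndarray) -> np.ndarray:
        return self.rotation_matrix.T @ np.asarray(d_scene, float)

    def direction_to_scene(self, d_eye: np.ndarray) -> np.ndarray:
        return self.rotation_matrix @ np.asarray(d_eye, float)

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit vector along the posed optical axis, pointing toward the scene."""
        return self.rotation_matrix @ np.array([0.0, 0.0, 1.0])

    def vertex_positions(self) -> np.ndarray:
        """(4, 3) surface vertex positions in the scene frame."""
        return np.stack(
            [self.to_scene(np.array([0.0, 0.0, s.vertex_z])) for s in self.surfaces]
        )

    @property
    def pupil_center(self) -> np.ndarray:
        return self.to_scene(np.array([0.0, 0.0, self.pupil_z]))


def rotate_eye(eye: EyeGeometry, theta_deg: float) -> EyeGeometry:
    """Rigidly rotate the eye by ``theta_deg`` in the horizontal plane."""
    total = eye.rotation_angle_deg + theta_deg
    if abs(total) >= 30.0:
        raise ParameterError(f"total rotation {total} deg outside |theta| < 30 deg")
    return replace(eye, rotation_angle_deg=total)


# ---------------------------------------------------------------------------
# Parameter file handling


class EyeParameters:
    """Validated accommodation-dependent eye parameters.

    Wraps the YAML parameter schema: per-surface rest-state radii, conics,
    apertures and thicknesses, per-medium indices with NIR offsets, and the
    log-law accommodation coefficients.  ``build(A)`` instantiates the
    concrete :class:`EyeGeometry` at accommodation ``A``.
    """

    def __init__(self, raw: Mapping[str, Any]):
        self._raw = dict(raw)
        try:
            self.axial_length = float(raw["axial_length_mm"])
            self.pupil_radius = float(raw["pupil_radius_mm"])
            self.rotation_center_z = float(raw["rotation_center_z_mm"])
            self.surfaces = [dict(s) for s in raw["surfaces"]]
            self.media = {k: dict(v) for k, v in raw["media"].items()}
            acc = raw["accommodation"]
            self.accommodation_law = str(acc.get("law", "linear"))
            self.acc_coefficients = {
                k: float(v) for k, v in acc["coefficients"].items()
            }
            self.lens_index_coeff = float(acc["lens_index_coeff"])
        except (KeyError, TypeError) as exc:
            raise ParameterError(f"malformed eye parameter file: {exc}") from exc
        if len(self.surfaces) != 4:
            raise ParameterError("eye parameter file must define 4 surfaces")
        for m in _MEDIA:
            if m not in self.media:
                raise ParameterError(f"missing medium {m!r}")
        if self.axial_length <= 0 or self.pupil_radius <= 0:
            raise ParameterError("axial length and pupil radius must be > 0")
        if self.accommodation_law not in ("linear", "log"):
            raise ParameterError("accommodation law must be 'linear' or 'log'")

    def index(self, medium: str) -> float:
        m = self.media[medium]
        return float(m["n_ref"]) + float(m.get("nir_offset", 0.0))

    def perturbed(
        self,
        radius_factors: Sequence[float] | None = None,
        thickness_factors: Sequence[float] | None = None,
        pupil_radius: float | None = None,
        max_fraction: float = 0.10,
    ) -> "EyeParameters":
        """Return a copy with per-surface multiplicative perturbations.

        Factors must stay within ``1 +/- max_fraction`` (anatomical
        plausibility bound on subject variation).
        """
        raw = yaml.safe_load(yaml.safe_dump(self._raw))  # deep copy
        for label, factors, key in (
            ("radius", radius_factors, "radius_mm"),
            ("thickness", thickness_factors, "thickness_mm"),
        ):
            if factors is None:
                continue
            if len(factors) != 4:
                raise ParameterError(f"{label}_factors must have length 4")
            for surf, f in zip(raw["surfaces"], factors):
                if abs(f - 1.0) > max_fraction + 1e-12:
                    raise ParameterError(
                        f"{label} factor {f} outside +/-{max_fraction:.0%} of default"
                    )
                if key in surf:
                    surf[key] = float(surf[key]) * float(f)
        if pupil_radius is not None:
            if pupil_radius <= 0:
                raise ParameterError("pupil_radius must be > 0")
            raw["pupil_radius_mm"] = float(pupil_radius)
        return EyeParameters(raw)

    # -- accommodation dependence ----------------------------------------

    def build(self, A: AccommodationState | float) -> EyeGeometry:
        if not isinstance(A, AccommodationState):
            A = AccommodationState(float(A))
        scale = math.log1p(A.A) if self.accommodation_law == "log" else A.A
        ll = self.acc_coefficients

        s = self.surfaces
        r = [float(x["radius_mm"]) for x in s]
        conic = [float(x["conic"]) for x in s]
        r[2] += ll["lens_anterior_radius"] * scale
        r[3] += ll["lens_posterior_radius"] * scale
        conic[2] += ll.get("lens_anterior_conic", 0.0) * scale

        t_cornea = float(s[0]["thickness_mm"])
        t_aqueous = float(s[1]["thickness_mm"]) + ll["anterior_chamber_depth"] * scale
        t_lens = float(s[2]["thickness_mm"]) + ll["lens_thickness"] * scale

        n_cornea = self.index("cornea")
        n_aqueous = self.index("aqueous")
        n_lens = self.index("lens") + self.lens_index_coeff * (10 * A.A + A.A**2)
        n_vitreous = self.index("vitreous")

        z1 = 0.0
        z2 = -t_cornea
        z3 = z2 - t_aqueous
        z4 = z3 - t_lens
        indices = [(1.0, n_cornea), (n_cornea, n_aqueous), (n_aqueous, n_lens), (n_lens, n_vitreous)]
        surfaces = tuple(
            SurfaceSpec(
                name=str(spec["name"]),
                vertex_z=z,
                radius=rad,
                conic=q,
                n_before=nb,
                n_after=na,
                aperture_radius=float(spec["aperture_radius_mm"]),
            )
            for spec, z, rad, q, (nb, na) in zip(s, (z1, z2, z3, z4), r, conic, indices)
        )
        return EyeGeometry(
            surfaces=surfaces,
            pupil_z=z3,  # iris plane at the anterior lens vertex
            pupil_radius=self.pupil_radius,
            axial_length=self.axial_length,
            rotation_center=np.array([0.0, 0.0, self.rotation_center_z]),
            accommodation=A.A,
        )


def load_eye_parameters(path: str | None = None) -> EyeParameters:
    """Load eye parameters from ``path`` or the packaged Navarro defaults."""
    if path is None:
        text = (
            resources.files("purkinjeye.data")
            .joinpath("navarro_accommodation.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return EyeParameters(yaml.safe_load(text))


def build_eye(
    A: AccommodationState | float, params: EyeParameters | None = None
) -> EyeGeometry:
    """Build the schematic eye at accommodation ``A`` [D].

    ``params`` supplies subject-specific overrides (see
    :meth:`EyeParameters.perturbed`); defaults to the packaged parameters.
    """
    if params is None:
        params = load_eye_parameters()
    return params.build(A)
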
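"""Scene description: NIR LED point source, pinhole camera, target array.

The camera is an ideal pinhole: a point aperture plus a sensor described by
its focal length in pixels and its pixel dimensions.  Sensor convention:
pixel origin at the top-left corner, x to the right, y downward,
coordinates continuous (sub-pixel).  World up (+y) therefore maps to
decreasing pixel y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .eye_model import GazeTarget, ParameterError

__all__ = ["SceneConfig", "load_scene", "scene_from_dict"]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of one measurement scene (all positions in mm, scene frame)."""

    led_position: np.ndarray
    camera_pinhole: np.ndarray
    camera_axis: np.ndarray  # unit vector, pinhole -> viewed scene
    focal_length_px: float
    sensor_size: tuple[int, int]  # (width_px, height_px)
    pixel_pitch: float = 0.006  # mm / px
    target_array: tuple[GazeTarget, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "led_position", np.asarray(self.led_position, float))
        object.__setattr__(self, "camera_pinhole", np.asarray(self.camera_pinhole, float))
        object.__setattr__(self, "camera_axis", _unit(self.camera_axis))
        if self.focal_length_px <= 0:
            raise ParameterError("focal_length_px must be > 0")
        w, h = self.sensor_size
        if w <= 0 or h <= 0:
            raise ParameterError("sensor dimensions must be positive")
        if self.pixel_pitch <= 0:
            raise ParameterError("pixel_pitch must be > 0")
        # both the camera and the LED must sit outside the eye (scene side)
        for label, p in (("camera", self.camera_pinhole), ("LED", self.led_position)):
            if np.linalg.norm(p) < 15.0:
                raise ParameterError(f"{label} position {p} lies inside the eye")

    # -- camera basis -----------------------------------------------------

    @property
    def camera_basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x_cam, y_cam, z_cam): image-right, image-down, viewing direction."""
        z = self.camera_axis
        x = _unit(np.cross(z, np.array([0.0, 1.0, 0.0])))
        y = np.cross(z, x)  # image-down (world-down for a level camera)
        return x, y, z

    @property
    def principal_point(self) -> tuple[float, float]:
        w, h = self.sensor_size
        return (w - 1) / 2.0, (h - 1) / 2.0

    def project_point(self, point: np.ndarray) -> tuple[float, float]:
        """Project a scene point through the pinhole onto the sensor [px]."""
        xb, yb, zb = self.camera_basis
        v = np.asarray(point, float) - self.camera_pinhole
        zc = float(v @ zb)
        if zc <= 0:
            raise ParameterError("point is behind the camera")
        cx, cy = self.principal_point
        return (
            cx + self.focal_length_px * float(v @ xb) / zc,
            cy + self.focal_length_px * float(v @ yb) / zc,
        )

    def project_incoming(self, direction: np.ndarray) -> tuple[float, float]:
        """Sensor position of a ray arriving at the pinhole along ``direction``
        (unit vector pointing toward the camera)."""
        return self.project_point(self.camera_pinhole - np.asarray(direction, float))

    def in_bounds(self, xy: tuple[float, float]) -> bool:
        w, h = self.sensor_size
        return 0 <= xy[0] <= w - 1 and 0 <= xy[1] <= h - 1


def scene_from_dict(raw: Mapping[str, Any]) -> SceneConfig:
    """Build a :class:`SceneConfig` from a parsed YAML mapping."""
    try:
        targets = tuple(
            GazeTarget(d=1.0 / float(t["depth_D"]), d_target=float(t.get("offset_m", 0.0)))
            for t in raw.get("target_array", [])
        )
        return SceneConfig(
            led_position=np.array(raw["led_position_mm"], float),
            camera_pinhole=np.array(raw["camera_pinhole_mm"], float),
            camera_axis=np.array(raw["camera_axis"], float),
            focal_length_px=float(raw["focal_length_px"]),
            sensor_size=(int(raw["sensor_size_px"][0]), int(raw["sensor_size_px"][1])),
            pixel_pitch=float(raw.get("pixel_pitch_mm", 0.006)),
            target_array=targets,
        )
    except (KeyError, TypeError, ZeroDivisionError) as exc:
        raise ParameterError(f"malformed scene config: {exc}") from exc


def load_scene(path: str | None = None) -> SceneConfig:
    """Load a scene from YAML, or the packaged default scene."""
    if path is None:
        text = resources.files("purkinjeye.data").joinpath("default_scene.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return scene_from_dict(yaml.safe_load(text))
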
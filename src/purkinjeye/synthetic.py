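"""Synthetic subjects, LED protocols, labeled sequences and rendered frames.

This module emulates the measurement campaign so that every downstream
stage (detection, analytic estimators, ML protocols) is testable without
human data: subjects are random anatomical perturbations of the schematic
eye, the LED protocol steps through target depths (default 4 -> 1 D in
0.5 D steps, 2 s per LED at 50 Hz, i.e. 100 frames per data point), the
eye follows each switch after a subject-specific reaction time, and the
10 measured parameters carry zero-mean measurement noise.  Frames recorded
before the eye reacts carry the previous eye state and a discard flag.

Noise is applied in feature space for sequences and in image space for
rendered frames, giving two independently testable paths.  Everything is
deterministic in the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .eye_model import (
    EyeParameters,
    GazeTarget,
    ParameterError,
    load_eye_parameters,
    rotation_angle,
)
from .raytrace import PupilObservation, PurkinjeSet, TraceError, simulate_observation
from .scene import SceneConfig

__all__ = [
    "SubjectParams",
    "ProtocolSpec",
    "RenderConfig",
    "PARAM_COLUMNS",
    "SEQUENCE_COLUMNS",
    "make_subject",
    "make_cohort",
    "make_session",
    "render_frame",
    "default_protocol",
    "save_sequence",
    "read_sequence",
]

#: The 10 measured parameters, in canonical column order [px].
PARAM_COLUMNS = (
    "x_PC_px",
    "y_PC_px",
    "r1_px",
    "r2_px",
    "x_P1_px",
    "y_P1_px",
    "x_P3_px",
    "y_P3_px",
    "x_P4_px",
    "y_P4_px",
)

SEQUENCE_COLUMNS = (
    "subject_id",
    "frame",
    "time_s",
    "target_A_D",
    "target_verg_deg",
    "eye_A_D",
    "eye_verg_deg",
    "discard",
    "blink",
    *PARAM_COLUMNS,
    "vis_P1",
    "vis_P3",
    "vis_P4",
)


@dataclass(frozen=True)
class SubjectParams:
    """Anatomical and behavioural parameters of one synthetic subject.

    Multiplicative per-surface perturbations stay within +/-10% of the
    schematic-eye defaults; reaction time lies in [150, 500] ms.
    """

    subject_id: str
    seed: int
    radius_factors: tuple[float, float, float, float]
    thickness_factors: tuple[float, float, float, float]
    pupil_radius_mm: float
    rotation_center_offset_mm: float
    reaction_time_ms: float
    feature_noise_px: float = 0.3
    blink_prob: float = 0.01

    def __post_init__(self) -> None:
        for f in (*self.radius_factors, *self.thickness_factors):
            if abs(f - 1.0) > 0.10 + 1e-12:
                raise ParameterError(f"perturbation factor {f} outside +/-10%")
        if not 150.0 <= self.reaction_time_ms <= 500.0:
            raise ParameterError("reaction_time_ms outside [150, 500] ms")
        if self.pupil_radius_mm <= 0 or self.feature_noise_px < 0:
            raise ParameterError("pupil radius must be > 0 and noise >= 0")

    def eye_parameters(self, base: EyeParameters | None = None) -> EyeParameters:
        base = base if base is not None else load_eye_parameters()
        p = base.perturbed(
            radius_factors=self.radius_factors,
            thickness_factors=self.thickness_factors,
            pupil_radius=self.pupil_radius_mm,
        )
        p.rotation_center_z = p.rotation_center_z + self.rotation_center_offset_mm
        return p


@dataclass(frozen=True)
class ProtocolSpec:
    """The LED stimulation protocol."""

    targets: tuple[GazeTarget, ...]
    dwell_s: float = 2.0
    frame_rate_hz: float = 50.0
    ordering: str = "sequential"  # or "randomized"
    discard_window_frames: int | None = None  # default: reaction time, rounded up

    def __post_init__(self) -> None:
        if not self.targets:
            raise ParameterError("protocol needs at least one target")
        if self.dwell_s <= 0 or self.frame_rate_hz <= 0:
            raise ParameterError("dwell and frame rate must be > 0")
        if self.ordering not in ("sequential", "randomized"):
            raise ParameterError("ordering must be 'sequential' or 'randomized'")

    @property
    def frames_per_step(self) -> int:
        return round(self.dwell_s * self.frame_rate_hz)


def default_protocol(scene: SceneConfig, ordering: str = "sequential") -> ProtocolSpec:
    """Protocol over the scene's target array (4 -> 1 D, 0.5 D steps)."""
    if not scene.target_array:
        raise ParameterError("scene has no target array")
    return ProtocolSpec(targets=tuple(scene.target_array), ordering=ordering)


# ---------------------------------------------------------------------------
# Subjects


def _truncnorm(rng: np.random.Generator, sd: float, bound: float) -> float:
    """Zero-mean truncated normal draw in [-bound, bound]."""
    for _ in range(100):
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return x
    return 0.0


def make_subject(
    seed: int,
    subject_id: str | None = None,
    anatomy_sd: float = 0.03,
    feature_noise_px: float = 0.3,
    blink_prob: float = 0.01,
) -> SubjectParams:
    """Draw one synthetic subject, deterministic in ``seed``.

    Radii and thicknesses receive truncated-normal multiplicative
    perturbations (sd ``anatomy_sd``, truncated at +/-9%); pupil radius,
    rotation-center offset and reaction time come from documented
    plausible ranges.  ``anatomy_sd=0`` reproduces the defaults exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([17, int(seed)]))
    bound = 0.09
    rad = tuple(1.0 + _truncnorm(rng, anatomy_sd, bound) for _ in range(4))
    thick = tuple(1.0 + _truncnorm(rng, anatomy_sd, bound) for _ in range(4))
    pupil = 2.5 + _truncnorm(rng, 0.2 * (anatomy_sd / 0.03 if anatomy_sd else 0.0), 0.5)
    rc_off = _truncnorm(rng, 0.3 * (anatomy_sd / 0.03 if anatomy_sd else 0.0), 0.9)
    reaction = float(np.clip(rng.normal(250.0, 60.0), 150.0, 500.0))
    return SubjectParams(
        subject_id=subject_id or f"S{seed:04d}",
        seed=int(seed),
        radius_factors=rad,
        thickness_factors=thick,
        pupil_radius_mm=float(pupil),
        rotation_center_offset_mm=float(rc_off),
        reaction_time_ms=reaction,
        feature_noise_px=feature_noise_px,
        blink_prob=blink_prob,
    )


def make_cohort(n: int, seed: int, **kwargs) -> list[SubjectParams]:
    """n subjects with per-subject seeds split off the root seed."""
    ss = np.random.SeedSequence(int(seed))
    child_seeds = ss.generate_state(n) % (2**31 - 1)
    return [
        make_subject(int(s), subject_id=f"S{i + 1:02d}", **kwargs)
        for i, s in enumerate(child_seeds)
    ]


# ---------------------------------------------------------------------------
# Sessions


def _observe(
    target: GazeTarget, params: EyeParameters, scene: SceneConfig
) -> tuple[PurkinjeSet, PupilObservation]:
    A = 1.0 / target.d  # accommodation depth follows the target distance
    return simulate_observation(A, target, scene, params)


def make_session(
    subject: SubjectParams,
    protocol: ProtocolSpec,
    scene: SceneConfig,
    base_params: EyeParameters | None = None,
    noise: bool = True,
    rep: int = 0,
) -> pd.DataFrame:
    """Simulate one recording session as a labeled feature sequence.

    One row per frame.  Rows within the reaction-time lag after a target
    switch keep the previous eye state and are flagged ``discard``.  With
    ``noise=True`` the 10 parameters receive zero-mean Gaussian noise of
    scale ``subject.feature_noise_px`` and rows blink out with probability
    ``subject.blink_prob`` (all parameters missing, flagged ``blink``).
    Deterministic given the subject seed, the protocol and ``rep`` (the
    repetition index: use distinct values for repeat or calibration
    sessions of the same subject).
    """
    rng = np.random.default_rng(np.random.SeedSequence([23, subject.seed, int(rep)]))
    params = subject.eye_parameters(base_params)

    order = list(protocol.targets)
    if protocol.ordering == "randomized":
        order = [order[i] for i in rng.permutation(len(order))]

    truths: dict[GazeTarget, tuple[PurkinjeSet, PupilObservation] | None] = {}
    for t in order:
        if t not in truths:
            try:
                truths[t] = _observe(t, params, scene)
            except TraceError:
                truths[t] = None

    n_step = protocol.frames_per_step
    if protocol.discard_window_frames is not None:
        n_lag = int(protocol.discard_window_frames)
    else:
        n_lag = math.ceil(subject.reaction_time_ms / 1000.0 * protocol.frame_rate_hz)
    dt = 1.0 / protocol.frame_rate_hz

    rows = []
    frame = 0
    prev: GazeTarget | None = None
    for step_target in order:
        for j in range(n_step):
            in_lag = j < n_lag and prev is not None
            state = prev if in_lag else step_target
            truth = truths.get(state) if state is not None else None
            row: dict = {
                "subject_id": subject.subject_id,
                "frame": frame,
                "time_s": frame * dt,
                "target_A_D": 1.0 / step_target.d,
                "target_verg_deg": rotation_angle(step_target),
                "eye_A_D": 1.0 / state.d if state else np.nan,
                "eye_verg_deg": rotation_angle(state) if state else np.nan,
                "discard": bool(j < n_lag),
                "blink": False,
            }
            if truth is None:
                vals = {c: np.nan for c in PARAM_COLUMNS}
                vis = {"vis_P1": False, "vis_P3": False, "vis_P4": False}
            else:
                pset, pupil = truth
                vals = {
                    "x_PC_px": pupil.x_PC,
                    "y_PC_px": pupil.y_PC,
                    "r1_px": pupil.r1,
                    "r2_px": pupil.r2,
                    "x_P1_px": pset.x_P1,
                    "y_P1_px": pset.y_P1,
                    "x_P3_px": pset.x_P3,
                    "y_P3_px": pset.y_P3,
                    "x_P4_px": pset.x_P4,
                    "y_P4_px": pset.y_P4,
                }
                vis = {
                    "vis_P1": pset.vis_P1,
                    "vis_P3": pset.vis_P3,
                    "vis_P4": pset.vis_P4,
                }
            if noise:
                eps = rng.normal(0.0, subject.feature_noise_px, size=len(PARAM_COLUMNS))
                vals = {c: v + e for (c, v), e in zip(vals.items(), eps)}
                if rng.random() < subject.blink_prob:
                    row["blink"] = True
                    vals = {c: np.nan for c in PARAM_COLUMNS}
                    vis = {"vis_P1": False, "vis_P3": False, "vis_P4": False}
            row.update(vals)
            row.update(vis)
            rows.append(row)
            frame += 1
        prev = step_target
    return pd.DataFrame(rows, columns=list(SEQUENCE_COLUMNS))


def save_sequence(df: pd.DataFrame, path: str) -> None:
    """Write a labeled sequence as CSV (units are in the column names:
    px, D, deg, s)."""
    df.to_csv(path, index=False)


def read_sequence(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SEQUENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"sequence file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Frame rendering


@dataclass(frozen=True)
class RenderConfig:
    """Appearance of synthetic NIR frames (8-bit grayscale levels)."""

    sensor_size: tuple[int, int] = (400, 300)
    background_level: float = 55.0
    iris_level: float = 95.0
    pupil_level: float = 22.0
    iris_radius_factor: float = 1.8  # iris radius as multiple of pupil r1
    spot_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"P1": 155.0, "P3": 110.0, "P4": 70.0}
    )
    spot_sigma_px: float = 1.6
    edge_softness_px: float = 0.7
    noise_gaussian_sigma: float = 2.0
    poisson_gain: float = 2.0  # photoelectrons per grey level; 0 disables

    def __post_init__(self) -> None:
        amps = self.spot_amplitudes
        if not amps.get("P1", 0) > amps.get("P3", 0) > amps.get("P4", 0):
            raise ParameterError("spot amplitudes must be ordered P1 > P3 > P4")


def render_frame(
    truth: tuple[PurkinjeSet, PupilObservation],
    cfg: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one synthetic NIR eye frame (uint8, shape (H, W)).

    Dark elliptical pupil on a brighter iris disc, Gaussian Purkinje spots
    (P1 brightest, then P3, then P4) at the truth positions, optional
    Gaussian + Poisson noise when ``rng`` is given.  Invisible or
    out-of-frame spots are silently omitted.  The pupil ellipse is drawn
    axis-aligned: the horizontal semi-axis is r2, the vertical r1 (eye
    rotation is horizontal, so foreshortening compresses x).
    """
    pset, pupil = truth
    w, h = cfg.sensor_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), cfg.background_level)

    def soft_disc(cx, cy, rx, ry):
        d = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
        return 1.0 / (1.0 + np.exp((d - 1.0) * max(rx, ry) / cfg.edge_softness_px))

    iris_r = cfg.iris_radius_factor * pupil.r1
    img += (cfg.iris_level - cfg.background_level) * soft_disc(
        pupil.x_PC, pupil.y_PC, iris_r, iris_r
    )
    img += (cfg.pupil_level - cfg.iris_level) * soft_disc(
        pupil.x_PC, pupil.y_PC, pupil.r2, pupil.r1
    )

    s2 = 2.0 * cfg.spot_sigma_px**2
    for name in ("P1", "P3", "P4"):
        x, y, vis = pset.spot(name)
        if not vis or not np.isfinite(x) or not np.isfinite(y):
            continue
        img += cfg.spot_amplitudes[name] * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / s2
        )

    if rng is not None:
        if cfg.poisson_gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * cfg.poisson_gain) / cfg.poisson_gain
        if cfg.noise_gaussian_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_gaussian_sigma, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
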
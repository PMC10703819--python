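"""Recover the 10 measurement parameters from a grayscale NIR eye frame.

The pupil is segmented as the largest plausible dark connected component
(darkest-class multi-Otsu threshold, holes closed so the bright Purkinje
spots inside the pupil do not split it) and summarised by a moments-based
ellipse: center (x_PC, y_PC) and semi-axes r1 >= r2.  Purkinje spots are
bright blobs above a percentile threshold inside a pupil-centred region of
interest; positions are intensity-weighted centroids of the
background-subtracted blob, and labels follow the configured assignment
strategy (P1 is always the brightest; by default the dimmer of the
remaining two is P4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .eye_model import ParameterError
from .raytrace import PupilObservation, PurkinjeSet
from .synthetic import PARAM_COLUMNS, SEQUENCE_COLUMNS

__all__ = [
    "DetectionConfig",
    "DetectionError",
    "detect_pupil",
    "detect_spots",
    "extract_sequence",
]


class DetectionError(RuntimeError):
    """Raised when the pupil or the required spots cannot be found."""


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for pupil and spot detection."""

    pupil_min_area_px2: float = 300.0
    pupil_max_area_frac: float = 0.5  # of the frame area
    spot_percentile: float = 99.0  # ROI intensity percentile for the threshold
    spot_min_area_px2: float = 3.0
    spot_max_area_px2: float = 400.0
    expected_spots: int = 3
    roi_axis_factor: float = 0.92  # ROI = pupil ellipse scaled by this factor
    assignment: str = "brightness-rank"  # or "prior-guided"

    def __post_init__(self) -> None:
        if not 50.0 < self.spot_percentile < 100.0:
            raise ParameterError("spot_percentile must be in (50, 100)")
        if self.expected_spots != 3:
            raise ParameterError("expected_spots must be 3 (P1, P3, P4)")
        if self.assignment not in ("brightness-rank", "prior-guided"):
            raise ParameterError("unknown assignment strategy")


def detect_pupil(image: np.ndarray, cfg: DetectionConfig = DetectionConfig()) -> PupilObservation:
    """Segment the dark pupil and fit its ellipse (moments-based).

    Raises :class:`DetectionError` when no dark region of plausible area
    exists (e.g. a uniform image).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ParameterError("empty image")
    if img.max() - img.min() < 1.0:
        raise DetectionError("pupil not found: image has no contrast")
    # darkest-class threshold: the pupil is darker than both iris and skin
    try:
        from skimage.filters import threshold_multiotsu

        thr = threshold_multiotsu(img, classes=3)[0]
    except ValueError:
        thr = threshold_otsu(img)
    mask = img < thr
    mask = ndimage.binary_fill_holes(mask)  # bright spots inside the pupil
    labels = sk_label(mask)
    best = None
    max_area = cfg.pupil_max_area_frac * img.size
    for region in regionprops(labels):
        if cfg.pupil_min_area_px2 <= region.area <= max_area:
            if best is None or region.area > best.area:
                best = region
    if best is None:
        raise DetectionError("pupil not found: no dark region of plausible area")
    cy, cx = best.centroid
    r1 = best.axis_major_length / 2.0
    r2 = best.axis_minor_length / 2.0
    if r2 <= 0:
        raise DetectionError("pupil not found: degenerate region")
    return PupilObservation(x_PC=float(cx), y_PC=float(cy), r1=float(r1), r2=float(r2))


def _blob_centroid(img: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Intensity-weighted centroid of a blob after local background
    subtraction; returns (x, y, flux).  The integrated flux, not the peak,
    ranks blob brightness: it is far more robust to shot noise."""
    dil = ndimage.binary_dilation(mask, iterations=2)
    ring = dil & ~mask
    background = np.median(img[ring]) if ring.any() else 0.0
    weights = np.clip(img - background, 0.0, None) * mask
    total = weights.sum()
    ys, xs = np.nonzero(mask)
    if total <= 0:
        return float(xs.mean()), float(ys.mean()), 0.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (
        float((weights * xx).sum() / total),
        float((weights * yy).sum() / total),
        float(total),
    )


def detect_spots(
    image: np.ndarray,
    pupil: PupilObservation,
    cfg: DetectionConfig = DetectionConfig(),
    prior: PurkinjeSet | None = None,
) -> PurkinjeSet:
    """Locate and label the Purkinje spots P1, P3, P4.

    P1 is the brightest blob.  The remaining two are assigned by
    ``cfg.assignment``: "brightness-rank" calls the dimmer one P4;
    "prior-guided" matches them to ``prior`` positions (falling back to
    brightness rank without a prior).  Missing spots yield
    ``visibility=False`` with NaN coordinates.
    """
    img = np.asarray(image, dtype=float)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    # search inside the pupil ellipse: the iris can outshine the dimmer
    # spots, so the ROI must exclude it (ellipse axis-aligned, x = r2)
    f = cfg.roi_axis_factor
    roi = ((xx - pupil.x_PC) / (f * pupil.r2)) ** 2 + (
        (yy - pupil.y_PC) / (f * pupil.r1)
    ) ** 2 <= 1.0
    if not roi.any():
        raise DetectionError("empty spot ROI")
    vals = img[roi]
    med, mx = np.median(vals), vals.max()
    # percentile threshold, floored well above the pupil background so a
    # sparse spot population cannot pull it into the noise
    thr = max(np.percentile(vals, cfg.spot_percentile), med + 0.25 * (mx - med))
    mask = (img > thr) & roi
    labels = sk_label(mask)
    blobs = []
    for region in regionprops(labels):
        if cfg.spot_min_area_px2 <= region.area <= cfg.spot_max_area_px2:
            blob_mask = labels == region.label
            x, y, flux = _blob_centroid(img, blob_mask)
            blobs.append({"x": x, "y": y, "flux": flux, "area": region.area})
    blobs.sort(key=lambda b: b["flux"], reverse=True)
    blobs = blobs[: cfg.expected_spots]

    out: dict = {}
    for name in ("P1", "P3", "P4"):
        out[f"x_{name}"] = math.nan
        out[f"y_{name}"] = math.nan
        out[f"vis_{name}"] = False

    if not blobs:
        return PurkinjeSet(**out)

    p1 = blobs[0]
    out.update(x_P1=p1["x"], y_P1=p1["y"], vis_P1=True)
    rest = blobs[1:]
    if len(rest) == 1:
        # a single remaining blob: label by brightness rank (P3 brighter)
        out.update(x_P3=rest[0]["x"], y_P3=rest[0]["y"], vis_P3=True)
    elif len(rest) == 2:
        if cfg.assignment == "prior-guided" and prior is not None and prior.vis_P3 and prior.vis_P4:
            d = lambda b, px, py: (b["x"] - px) ** 2 + (b["y"] - py) ** 2
            cost_a = d(rest[0], prior.x_P3, prior.y_P3) + d(rest[1], prior.x_P4, prior.y_P4)
            cost_b = d(rest[1], prior.x_P3, prior.y_P3) + d(rest[0], prior.x_P4, prior.y_P4)
            p3, p4 = (rest[0], rest[1]) if cost_a <= cost_b else (rest[1], rest[0])
        else:
            p3, p4 = (rest[0], rest[1]) if rest[0]["flux"] >= rest[1]["flux"] else (rest[1], rest[0])
        out.update(x_P3=p3["x"], y_P3=p3["y"], vis_P3=True)
        out.update(x_P4=p4["x"], y_P4=p4["y"], vis_P4=True)
    return PurkinjeSet(**out)


def extract_sequence(
    frames,
    cfg: DetectionConfig = DetectionConfig(),
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run detection over time-ordered frames and assemble the feature table.

    ``meta`` (optional) supplies per-frame label columns (targets, eye
    state) copied through from the generator; detection failures flag the
    row rather than aborting the sequence.  Output schema matches the
    synthetic LabeledSequence, so detected and simulated data interchange.
    """
    rows = []
    prior: PurkinjeSet | None = None
    for i, frame in enumerate(frames):
        row: dict = {c: np.nan for c in SEQUENCE_COLUMNS}
        row.update(
            subject_id="", frame=i, discard=False, blink=False,
            vis_P1=False, vis_P3=False, vis_P4=False,
        )
        if meta is not None:
            for c in meta.columns:
                if c in SEQUENCE_COLUMNS:
                    row[c] = meta.iloc[i][c]
        try:
            pupil = detect_pupil(frame, cfg)
            pset = detect_spots(frame, pupil, cfg, prior=prior)
            if pset.vis_P1 and pset.vis_P3 and pset.vis_P4:
                prior = pset
            row.update(
                x_PC_px=pupil.x_PC, y_PC_px=pupil.y_PC,
                r1_px=pupil.r1, r2_px=pupil.r2,
                x_P1_px=pset.x_P1, y_P1_px=pset.y_P1,
                x_P3_px=pset.x_P3, y_P3_px=pset.y_P3,
                x_P4_px=pset.x_P4, y_P4_px=pset.y_P4,
                vis_P1=pset.vis_P1, vis_P3=pset.vis_P3, vis_P4=pset.vis_P4,
            )
        except DetectionError:
            row["blink"] = True  # no usable eye in this frame
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SEQUENCE_COLUMNS))
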
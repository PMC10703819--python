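"""Closed-form accommodation and vergence estimators, plus correlation
analysis of candidate features.

The accommodation feature is the signed vertical distance between the lens
reflections, ``y_P4 - y_P3`` [px]; the vergence feature is the Euclidean
distance between a spot pair (P3-P4 by default, P1-P4 selectable).  Each
maps to its target through a per-subject straight line parameterised by a
slope ``a`` and an x-intercept ``b``:

    predicted depth  [D]   = a_acc * ((y_P4 - y_P3) - b_acc)
    predicted angle  [deg] = a_ver * (d(pair)       - b_ver)

Fitting is ordinary least squares in that parameterisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .eye_model import ParameterError

__all__ = [
    "LinearModel",
    "FitError",
    "accommodation_feature",
    "vergence_feature",
    "fit_linear",
    "predict",
    "correlation_matrix",
    "CANDIDATE_FEATURES",
]

FeatureChoice = Literal["P3P4", "P1P4"]


class FitError(ValueError):
    """Raised for degenerate fits (constant feature, too few levels)."""


@dataclass(frozen=True)
class LinearModel:
    """target = a * (feature - b); slope ``a`` [D/px or deg/px],
    x-intercept ``b`` [px]."""

    a: float
    b: float
    rmse: float = math.nan  # residual RMSE of the fit, target units
    n: int = 0
    feature_choice: str | None = None

    def __post_init__(self) -> None:
        if self.a == 0:
            raise FitError("degenerate linear model: zero slope")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "rmse": self.rmse,
            "n": self.n,
            "feature_choice": self.feature_choice,
        }


def _pair_distance(row, p: str, q: str) -> float:
    if not (row[f"vis_{p}"] and row[f"vis_{q}"]):
        return math.nan
    return math.hypot(
        row[f"x_{p}_px"] - row[f"x_{q}_px"], row[f"y_{p}_px"] - row[f"y_{q}_px"]
    )


def accommodation_feature(row) -> float:
    """Signed vertical P3-P4 separation, ``y_P4 - y_P3`` [px]; NaN if either
    lens reflection is missing."""
    if not (row["vis_P3"] and row["vis_P4"]):
        return math.nan
    return float(row["y_P4_px"] - row["y_P3_px"])


def vergence_feature(row, feature_choice: FeatureChoice = "P3P4") -> float:
    """Euclidean distance [px] between the chosen spot pair; NaN when a spot
    is missing."""
    if feature_choice == "P3P4":
        return _pair_distance(row, "P3", "P4")
    if feature_choice == "P1P4":
        return _pair_distance(row, "P1", "P4")
    raise ParameterError(f"unknown feature_choice {feature_choice!r}")


def fit_linear(
    features: np.ndarray, targets: np.ndarray, feature_choice: str | None = None
) -> LinearModel:
    """Least-squares fit of target = a * (feature - b).

    Requires at least two distinct target levels and a non-constant
    feature.  NaN pairs are excluded.
    """
    f = np.asarray(features, float)
    t = np.asarray(targets, float)
    ok = np.isfinite(f) & np.isfinite(t)
    f, t = f[ok], t[ok]
    if np.unique(t).size < 2:
        raise FitError("need at least 2 distinct target levels")
    if np.ptp(f) == 0:
        raise FitError("degenerate fit: constant feature")
    slope, intercept = np.polyfit(f, t, 1)
    if slope == 0:
        raise FitError("degenerate fit: zero slope")
    resid = t - (slope * f + intercept)
    return LinearModel(
        a=float(slope),
        b=float(-intercept / slope),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=int(f.size),
        feature_choice=feature_choice,
    )


def predict(model: LinearModel, feature) -> np.ndarray | float:
    """Apply the linear map a * (feature - b); NaN features give NaN."""
    f = np.asarray(feature, float)
    out = model.a * (f - model.b)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Correlation analysis

#: Candidate features screened against the targets, as callables on a row.
CANDIDATE_FEATURES: dict = {
    "y_P4-y_P3": accommodation_feature,
    "x_P4-x_P3": lambda r: (r["x_P4_px"] - r["x_P3_px"]) if (r["vis_P3"] and r["vis_P4"]) else math.nan,
    "d(P3-P4)": lambda r: _pair_distance(r, "P3", "P4"),
    "d(P1-P4)": lambda r: _pair_distance(r, "P1", "P4"),
    "d(P1-P3)": lambda r: _pair_distance(r, "P1", "P3"),
    "y_P3-y_P1": lambda r: (r["y_P3_px"] - r["y_P1_px"]) if (r["vis_P1"] and r["vis_P3"]) else math.nan,
    "x_P4-x_P1": lambda r: (r["x_P4_px"] - r["x_P1_px"]) if (r["vis_P1"] and r["vis_P4"]) else math.nan,
    "x_P1": lambda r: r["x_P1_px"] if r["vis_P1"] else math.nan,
    "y_P1": lambda r: r["y_P1_px"] if r["vis_P1"] else math.nan,
    "x_PC": lambda r: r["x_PC_px"],
    "y_PC": lambda r: r["y_PC_px"],
    "r1": lambda r: r["r1_px"],
    "r2": lambda r: r["r2_px"],
}


def correlation_matrix(
    sequence: pd.DataFrame,
    targets: tuple[str, str] = ("target_A_D", "target_verg_deg"),
    include_discarded: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each candidate feature against the targets.

    Rows with missing values are excluded pairwise; zero-variance features
    yield NaN entries.  Requires at least 3 usable rows per entry.
    """
    df = sequence if include_discarded else sequence[~sequence["discard"]]
    if len(df) < 3:
        raise ParameterError("need at least 3 rows for correlation analysis")
    out = {}
    for name, fn in CANDIDATE_FEATURES.items():
        vals = df.apply(fn, axis=1).astype(float)
        row = {}
        for tcol in targets:
            t = df[tcol].astype(float)
            ok = vals.notna() & t.notna()
            if ok.sum() < 3 or vals[ok].std() == 0 or t[ok].std() == 0:
                row[tcol] = math.nan
            else:
                row[tcol] = float(stats.pearsonr(vals[ok], t[ok]).statistic)
        out[name] = row
    return pd.DataFrame(out).T
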
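"""MLP regression protocols, two-point calibration, and evaluation.

Two training protocols mirror the measurement study:

* **own-data**: a seeded random 30% of one subject's frames trains a
  multi-layer perceptron (after grid-search hyperparameter tuning); the
  model is then evaluated on the subject's entire sequence.  An optional
  leak-free mode evaluates on the held-out 70% only.
* **LOSO**: leave-one-subject-out cross-validation.  Per fold the model is
  tuned and trained on all other subjects and evaluated on the held-out
  subject after a two-point calibration: the subject fixates two known
  depths (3.5 D and 1.5 D by default) and the raw predictions are mapped
  by the affine transform sending the predictions at those points onto
  their targets,

      (A_CP1t - A_calib) / (A_CP1p - A_pred) = (A_calib - A_CP2t) / (A_pred - A_CP2p)

  whose closed-form solution is
      A_calib = (A_CP1t (A_pred - A_CP2p) + A_CP2t (A_CP1p - A_pred)) / (A_CP1p - A_CP2p)
  and likewise for the vergence angle.

One network jointly predicts both outputs (depth [D], vergence [deg]).
Headline RMSEs are computed on per-target mean predictions over the
non-discarded frames, matching how the target test points are scored.
All randomness flows from explicit seeds; refits are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import clone
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .eye_model import ParameterError
from .synthetic import PARAM_COLUMNS

__all__ = [
    "SUBSETS",
    "MLPConfig",
    "CalibrationMap",
    "EvalReport",
    "usable_rows",
    "train_own_data",
    "train_loso",
    "two_point_calibrate",
    "calibration_session",
    "permutation_importance",
    "rmse",
    "pearson_repeatability",
]

#: Input-feature subsets: Purkinje spots only (6) or spots + pupil (10).
SUBSETS: dict[str, tuple[str, ...]] = {
    "purkinje": ("x_P1_px", "y_P1_px", "x_P3_px", "y_P3_px", "x_P4_px", "y_P4_px"),
    "purkinje+pupil": PARAM_COLUMNS[4:] + PARAM_COLUMNS[:4],
}

TARGET_COLUMNS = ("target_A_D", "target_verg_deg")


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameter grid and training controls for the MLP protocols.

    The tuned quantities are the hidden-layer layout, batch size and epoch
    budget; tuning is a grid search with ``cv_folds``-fold cross-validation
    minimising the summed squared error of both outputs.
    """

    hidden_options: tuple[tuple[int, ...], ...] = ((32,), (64, 32))
    batch_options: tuple[int, ...] = (32,)
    epoch_options: tuple[int, ...] = (200,)
    cv_folds: int = 3
    tol: float = 1e-4
    n_iter_no_change: int = 10
    early_stopping: bool = True  # hold out 10% of training rows to stop early

    def grid(self) -> dict:
        return {
            "mlp__hidden_layer_sizes": list(self.hidden_options),
            "mlp__batch_size": list(self.batch_options),
            "mlp__max_iter": list(self.epoch_options),
        }


def _pipeline(seed: int, cfg: MLPConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPRegressor(
                    random_state=int(seed) % (2**31 - 1),
                    tol=cfg.tol,
                    n_iter_no_change=cfg.n_iter_no_change,
                    early_stopping=cfg.early_stopping,
                ),
            ),
        ]
    )


def usable_rows(df: pd.DataFrame, subset: str = "purkinje") -> pd.DataFrame:
    """Non-discarded, non-blink rows with all selected inputs finite."""
    cols = list(SUBSETS[subset])
    ok = (~df["discard"]) & (~df["blink"]) & df["vis_P1"] & df["vis_P3"] & df["vis_P4"]
    ok &= np.isfinite(df[cols]).all(axis=1)
    return df[ok]


@dataclass
class EvalReport:
    """Evaluation of one fitted model on one subject's sequence."""

    subject_id: str
    subset: str
    rmse_depth_D: float
    rmse_angle_deg: float
    rmse_depth_frames_D: float
    rmse_angle_frames_deg: float
    per_target: pd.DataFrame
    best_params: dict
    n_train: int
    n_eval: int
    calibrated: bool = False

    def summary(self) -> str:
        lines = [
            f"subject {self.subject_id} ({self.subset}"
            + (", calibrated)" if self.calibrated else ")"),
            f"  depth RMSE (target means): {self.rmse_depth_D:.3f} D",
            f"  angle RMSE (target means): {self.rmse_angle_deg:.3f} deg",
            f"  depth RMSE (frames):       {self.rmse_depth_frames_D:.3f} D",
            f"  angle RMSE (frames):       {self.rmse_angle_frames_deg:.3f} deg",
            f"  n_train={self.n_train}  n_eval={self.n_eval}  best={self.best_params}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Metrics


def rmse(predictions, targets) -> float:
    """Root-mean-square error over aligned finite pairs."""
    p = np.asarray(predictions, float)
    t = np.asarray(targets, float)
    ok = np.isfinite(p) & np.isfinite(t)
    if not ok.any():
        raise ParameterError("rmse: no overlapping finite pairs")
    return float(np.sqrt(np.mean((p[ok] - t[ok]) ** 2)))


def pearson_repeatability(run1, run2) -> float:
    """Pearson r between two repeated runs' predictions."""
    a = np.asarray(run1, float)
    b = np.asarray(run2, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ParameterError("repeatability: need >= 3 overlapping pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ParameterError("repeatability: zero-variance run")
    return float(stats.pearsonr(a, b).statistic)


def _evaluate(
    model: Pipeline,
    eval_df: pd.DataFrame,
    subset: str,
    subject_id: str,
    best_params: dict,
    n_train: int,
    calibration: "CalibrationMap | None" = None,
) -> EvalReport:
    X = eval_df[list(SUBSETS[subset])].to_numpy()
    pred = model.predict(X)
    if calibration is not None:
        a, v = two_point_calibrate(calibration, pred[:, 0], pred[:, 1])
        pred = np.column_stack([a, v])
    out = eval_df[["target_A_D", "target_verg_deg"]].copy()
    out["pred_A_D"] = pred[:, 0]
    out["pred_verg_deg"] = pred[:, 1]
    per_target = (
        out.groupby(["target_A_D", "target_verg_deg"], as_index=False)
        .mean()
        .sort_values("target_A_D", ignore_index=True)
    )
    angle_constant = out["target_verg_deg"].std() == 0
    return EvalReport(
        subject_id=subject_id,
        subset=subset,
        rmse_depth_D=rmse(per_target["pred_A_D"], per_target["target_A_D"]),
        rmse_angle_deg=rmse(per_target["pred_verg_deg"], per_target["target_verg_deg"]),
        rmse_depth_frames_D=rmse(out["pred_A_D"], out["target_A_D"]),
        rmse_angle_frames_deg=rmse(out["pred_verg_deg"], out["target_verg_deg"]),
        per_target=per_target,
        best_params=dict(best_params),
        n_train=n_train,
        n_eval=len(eval_df),
        calibrated=calibration is not None,
    )


# ---------------------------------------------------------------------------
# Own-data protocol


def _grid_fit(
    X: np.ndarray, y: np.ndarray, seed: int, cfg: MLPConfig
) -> tuple[Pipeline, dict]:
    grid = cfg.grid()
    n_candidates = int(np.prod([len(v) for v in grid.values()]))
    base = _pipeline(seed, cfg)
    # early stopping needs a meaningful validation split; below ~120 rows the
    # 10% holdout degenerates, so fall back to tol-based convergence
    if cfg.early_stopping and len(X) < 120:
        base.set_params(mlp__early_stopping=False)
    if n_candidates == 1:
        params = {k: v[0] for k, v in grid.items()}
        model = clone(base).set_params(**params)
        model.fit(X, y)
        return model, params
    search = GridSearchCV(
        base,
        grid,
        cv=KFold(cfg.cv_folds, shuffle=True, random_state=int(seed) % (2**31 - 1)),
        scoring="neg_mean_squared_error",
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def train_own_data(
    sequence: pd.DataFrame,
    subset: str = "purkinje",
    seed: int = 0,
    cfg: MLPConfig = MLPConfig(),
    train_fraction: float = 0.3,
    leak_free: bool = False,
) -> tuple[Pipeline, EvalReport]:
    """Train on a seeded 30% of one subject's frames, evaluate per protocol.

    ``leak_free=False`` evaluates on the entire sequence (training frames
    included), as the measurement protocol specifies; ``leak_free=True``
    evaluates on the held-out 70% only.
    """
    df = usable_rows(sequence, subset)
    if df["target_A_D"].nunique() < 2:
        raise ParameterError("own-data training needs >= 2 target levels")
    rng = np.random.default_rng(np.random.SeedSequence([31, int(seed)]))
    n_train = max(2, int(round(train_fraction * len(df))))
    idx = rng.permutation(len(df))
    train_df = df.iloc[idx[:n_train]]
    eval_df = df.iloc[idx[n_train:]] if leak_free else df
    cols = list(SUBSETS[subset])
    model, best = _grid_fit(
        train_df[cols].to_numpy(), train_df[list(TARGET_COLUMNS)].to_numpy(), seed, cfg
    )
    sid = str(df["subject_id"].iloc[0]) if len(df) else ""
    return model, _evaluate(model, eval_df, subset, sid, best, n_train)


def predict_sequence(
    model: Pipeline, sequence: pd.DataFrame, subset: str = "purkinje"
) -> pd.DataFrame:
    """Append ``pred_A_D``/``pred_verg_deg`` columns (NaN on unusable rows)."""
    out = sequence.copy()
    out["pred_A_D"] = np.nan
    out["pred_verg_deg"] = np.nan
    df = usable_rows(sequence, subset)
    if len(df):
        pred = model.predict(df[list(SUBSETS[subset])].to_numpy())
        out.loc[df.index, "pred_A_D"] = pred[:, 0]
        out.loc[df.index, "pred_verg_deg"] = pred[:, 1]
    return out


# ---------------------------------------------------------------------------
# Two-point calibration


@dataclass(frozen=True)
class CalibrationMap:
    """Raw-prediction -> calibrated-output map anchored at two fixation
    points (targets and the model's mean predictions there)."""

    A_cp_target: tuple[float, float]
    A_cp_pred: tuple[float, float]
    V_cp_target: tuple[float, float]
    V_cp_pred: tuple[float, float]

    def __post_init__(self) -> None:
        if math.isclose(self.A_cp_pred[0], self.A_cp_pred[1]):
            raise ParameterError("degenerate calibration: equal depth predictions")
        if math.isclose(self.V_cp_pred[0], self.V_cp_pred[1]):
            raise ParameterError("degenerate calibration: equal vergence predictions")


def _affine_cal(t1, p1, t2, p2, pred):
    return (t1 * (pred - p2) + t2 * (p1 - pred)) / (p1 - p2)


def two_point_calibrate(cal: CalibrationMap, A_pred, V_pred):
    """Calibrated (A, V): the affine map sending the calibration-point
    predictions onto their targets (closed form of the anchored
    proportion)."""
    A = _affine_cal(*_flat(cal.A_cp_target, cal.A_cp_pred), np.asarray(A_pred, float))
    V = _affine_cal(*_flat(cal.V_cp_target, cal.V_cp_pred), np.asarray(V_pred, float))
    return A, V


def _flat(t, p):
    return t[0], p[0], t[1], p[1]


def two_point_calibrate_numeric(cal: CalibrationMap, A_pred: float, V_pred: float):
    """Independent root-finding solution of the calibration proportion
    (cross-check for the closed form)."""

    def solve(t, p, x):
        def fun(c):
            return (t[0] - c) * (x - p[1]) - (c - t[1]) * (p[0] - x)

        return optimize.brentq(fun, -1e4, 1e4)

    return solve(cal.A_cp_target, cal.A_cp_pred, A_pred), solve(
        cal.V_cp_target, cal.V_cp_pred, V_pred
    )


def calibration_session(
    model: Pipeline,
    calib_df: pd.DataFrame,
    subset: str = "purkinje",
    cp_depths: tuple[float, float] = (3.5, 1.5),
) -> CalibrationMap:
    """Build the two-point calibration from a subject's fixation frames at
    the calibration depths (default 3.5 D and 1.5 D).

    Per point, the raw model predictions are averaged over the
    non-discarded frames.
    """
    df = usable_rows(calib_df, subset)
    cols = list(SUBSETS[subset])
    a_t, a_p, v_t, v_p = [], [], [], []
    for depth in cp_depths:
        pt = df[np.isclose(df["target_A_D"], depth)]
        if len(pt) == 0:
            raise ParameterError(f"no calibration frames at {depth} D")
        pred = model.predict(pt[cols].to_numpy()).mean(axis=0)
        a_t.append(float(depth))
        v_t.append(float(pt["target_verg_deg"].mean()))
        a_p.append(float(pred[0]))
        v_p.append(float(pred[1]))
    if math.isclose(v_t[0], v_t[1], abs_tol=1e-9):
        # accommodation-only protocol: both calibration points share one
        # vergence target, so vergence passes through uncalibrated
        v_t, v_p = [0.0, 1.0], [0.0, 1.0]
    return CalibrationMap(
        A_cp_target=(a_t[0], a_t[1]),
        A_cp_pred=(a_p[0], a_p[1]),
        V_cp_target=(v_t[0], v_t[1]),
        V_cp_pred=(v_p[0], v_p[1]),
    )


# ---------------------------------------------------------------------------
# LOSO protocol


def train_loso(
    cohort: pd.DataFrame,
    calibration: Mapping[str, pd.DataFrame],
    subset: str = "purkinje",
    seed: int = 0,
    cfg: MLPConfig = MLPConfig(),
    calibrate: bool = True,
) -> list[tuple[Pipeline, EvalReport]]:
    """Leave-one-subject-out cross-validation with two-point calibration.

    ``cohort`` concatenates all subjects' sequences (column
    ``subject_id``); ``calibration`` maps subject id to that subject's
    calibration-session frames.  Per fold the grid search and training see
    only the other subjects' rows (audited); the held-out subject is
    evaluated after calibration.  Folds whose subject misses target levels
    or calibration data are skipped with a warning.
    """
    subjects = list(dict.fromkeys(cohort["subject_id"]))
    if len(subjects) < 3:
        raise ParameterError("LOSO needs at least 3 subjects")
    cols = list(SUBSETS[subset])
    results = []
    for i, held_out in enumerate(subjects):
        train_df = usable_rows(cohort[cohort["subject_id"] != held_out], subset)
        test_df = usable_rows(cohort[cohort["subject_id"] == held_out], subset)
        assert held_out not in set(train_df["subject_id"])  # LOSO hygiene audit
        if test_df["target_A_D"].nunique() < 2 or len(test_df) == 0:
            import warnings

            warnings.warn(f"skipping LOSO fold {held_out}: missing target levels")
            continue
        fold_seed = np.random.SeedSequence([41, int(seed), i]).generate_state(1)[0] % (
            2**31 - 1
        )
        model, best = _grid_fit(
            train_df[cols].to_numpy(),
            train_df[list(TARGET_COLUMNS)].to_numpy(),
            int(fold_seed),
            cfg,
        )
        cal = None
        if calibrate:
            if held_out not in calibration:
                raise ParameterError(f"no calibration session for {held_out}")
            cal = calibration_session(model, calibration[held_out], subset)
        report = _evaluate(
            model, test_df, subset, str(held_out), best, len(train_df), calibration=cal
        )
        results.append((model, report))
    return results


# ---------------------------------------------------------------------------
# Permutation importance


def permutation_importance(
    model: Pipeline,
    sequence: pd.DataFrame,
    subset: str = "purkinje",
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Normalized permutation importance of each input feature.

    Shuffles one input column at a time (seeded, ``n_repeats`` times) and
    measures the increase in summed-output mean squared error; weights are
    scaled so the maximum equals 1.  Constant columns get zero importance.
    """
    df = usable_rows(sequence, subset)
    cols = list(SUBSETS[subset])
    X = df[cols].to_numpy()
    y = df[list(TARGET_COLUMNS)].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([53, int(seed)]))
    base_err = np.mean((model.predict(X) - y) ** 2)
    drops = np.zeros((len(cols), n_repeats))
    for j, col in enumerate(cols):
        if np.ptp(X[:, j]) == 0:
            continue  # constant column: zero importance
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j, r] = np.mean((model.predict(Xp) - y) ** 2) - base_err
    mean = np.clip(drops.mean(axis=1), 0.0, None)
    std = drops.std(axis=1)
    peak = mean.max()
    if peak <= 0:
        weights = np.zeros_like(mean)
        std_n = np.zeros_like(std)
    else:
        weights = mean / peak
        std_n = std / peak
    return pd.DataFrame(
        {"feature": cols, "weight": weights, "std": std_n, "constant": [np.ptp(X[:, j]) == 0 for j in range(len(cols))]}
    ).set_index("feature")
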
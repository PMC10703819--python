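"""MLP protocols, two-point calibration algebra, importance, and metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from purkinjeye.eye_model import GazeTarget, ParameterError
from purkinjeye.ml import (
    SUBSETS,
    CalibrationMap,
    MLPConfig,
    calibration_session,
    pearson_repeatability,
    permutation_importance,
    predict_sequence,
    rmse,
    train_loso,
    train_own_data,
    two_point_calibrate,
    two_point_calibrate_numeric,
)
from purkinjeye.synthetic import ProtocolSpec, make_cohort, make_session, make_subject

FAST = MLPConfig(hidden_options=((16,),), cv_folds=2)


def _random_map(rng):
    while True:
        a_p = rng.normal(size=2) * 3
        v_p = rng.normal(size=2) * 3
        if abs(a_p[0] - a_p[1]) > 0.1 and abs(v_p[0] - v_p[1]) > 0.1:
            return CalibrationMap(
                A_cp_target=tuple(rng.normal(size=2) * 2),
                A_cp_pred=tuple(a_p),
                V_cp_target=tuple(rng.normal(size=2) * 2),
                V_cp_pred=tuple(v_p),
            )


class TestCalibrationAlgebra:
    def test_fixed_points(self):
        cal = CalibrationMap((3.5, 1.5), (3.2, 1.9), (6.3, 2.7), (6.0, 3.1))
        a, v = two_point_calibrate(cal, 3.2, 6.0)
        assert a == pytest.approx(3.5) and v == pytest.approx(6.3)
        a, v = two_point_calibrate(cal, 1.9, 3.1)
        assert a == pytest.approx(1.5) and v == pytest.approx(2.7)

    def test_midpoint_maps_to_midpoint(self):
        cal = CalibrationMap((3.5, 1.5), (3.2, 1.9), (6.3, 2.7), (6.0, 3.1))
        a, v = two_point_calibrate(cal, (3.2 + 1.9) / 2, (6.0 + 3.1) / 2)
        assert a == pytest.approx((3.5 + 1.5) / 2)
        assert v == pytest.approx((6.3 + 2.7) / 2)

    def test_closed_form_matches_numeric_root(self, rng):
        for _ in range(300):
            cal = _random_map(rng)
            ap, vp = rng.normal(), rng.normal()
            a1, v1 = two_point_calibrate(cal, ap, vp)
            a2, v2 = two_point_calibrate_numeric(cal, ap, vp)
            assert abs(a1 - a2) < 1e-9 and abs(v1 - v2) < 1e-9

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(ParameterError):
            CalibrationMap((3.5, 1.5), (2.0, 2.0), (6.0, 3.0), (5.0, 4.0))


class _AffineModel:
    """Stand-in regressor applying an affine distortion to known targets."""

    def __init__(self, df, gain=1.0, bias=0.0):
        self.lookup = df.set_index("frame")[["target_A_D", "target_verg_deg"]]
        self.gain, self.bias = gain, bias
        self.df = df

    def predict(self, X):
        # identify rows by matching the input features back to the frame
        cols = list(SUBSETS["purkinje"])
        idx = []
        arr = self.df[cols].to_numpy()
        for x in X:
            idx.append(int(np.argmin(((arr - x) ** 2).sum(axis=1))))
        t = self.df.iloc[idx][["target_A_D", "target_verg_deg"]].to_numpy()
        return self.gain * t + self.bias


@pytest.fixture(scope="module")
def calib_df(scene):
    proto = ProtocolSpec(
        targets=(GazeTarget(1 / 3.5, 0.0315), GazeTarget(1 / 1.5, 0.0315)),
        dwell_s=0.3,
        discard_window_frames=2,
    )
    subj = make_subject(4, feature_noise_px=0.0, blink_prob=0.0)
    return make_session(subj, proto, scene, noise=False)


class TestCalibrationSession:
    def test_perfect_model_gives_identity(self, calib_df):
        model = _AffineModel(calib_df)
        cal = calibration_session(model, calib_df)
        a, _ = two_point_calibrate(cal, np.array([2.0, 3.0]), np.array([4.0, 4.0]))
        assert a == pytest.approx([2.0, 3.0])

    def test_constant_bias_removed(self, calib_df):
        model = _AffineModel(calib_df, bias=0.5)
        cal = calibration_session(model, calib_df)
        a, _ = two_point_calibrate(cal, 3.5 + 0.5, 0.0)
        assert a == pytest.approx(3.5)

    def test_gain_error_corrected_at_anchors(self, calib_df):
        model = _AffineModel(calib_df, gain=1.2)
        cal = calibration_session(model, calib_df)
        a, _ = two_point_calibrate(cal, 1.2 * 1.5, 0.0)
        assert a == pytest.approx(1.5)
        a, _ = two_point_calibrate(cal, 1.2 * 3.5, 0.0)
        assert a == pytest.approx(3.5)

    def test_missing_point_rejected(self, calib_df):
        model = _AffineModel(calib_df)
        with pytest.raises(ParameterError, match="no calibration frames"):
            calibration_session(model, calib_df, cp_depths=(3.5, 2.0))


class TestMetrics:
    def test_rmse_trivial_cases(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.5, 2.5], [1.0, 2.0]) == pytest.approx(0.5)
        with pytest.raises(ParameterError):
            rmse([math.nan], [1.0])

    def test_repeatability(self):
        x = np.linspace(0, 1, 20)
        assert pearson_repeatability(x, x) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            pearson_repeatability(np.ones(10), np.ones(10))


class TestOwnData:
    def test_seeded_determinism(self, session_df):
        _, r1 = train_own_data(session_df, seed=5, cfg=FAST)
        _, r2 = train_own_data(session_df, seed=5, cfg=FAST)
        assert r1.rmse_depth_D == r2.rmse_depth_D
        assert r1.rmse_angle_deg == r2.rmse_angle_deg

    def test_noiseless_subject_near_interpolation(self, scene, short_protocol):
        subj = make_subject(3, feature_noise_px=0.0, blink_prob=0.0)
        df = make_session(subj, short_protocol, scene, noise=False)
        cfg = MLPConfig(hidden_options=((32,),), epoch_options=(600,), cv_folds=2,
                        early_stopping=False)
        _, report = train_own_data(df, seed=0, cfg=cfg)
        assert report.rmse_depth_D < 0.05

    def test_leak_free_mode_excludes_training_rows(self, session_df):
        _, full = train_own_data(session_df, seed=1, cfg=FAST)
        _, holdout = train_own_data(session_df, seed=1, cfg=FAST, leak_free=True)
        assert holdout.n_eval < full.n_eval
        assert holdout.n_eval + full.n_train == full.n_eval

    def test_too_few_levels_rejected(self, session_df):
        one = session_df[session_df["target_A_D"] == 4.0]
        with pytest.raises(ParameterError):
            train_own_data(one, seed=0, cfg=FAST)

    def test_predict_sequence_appends_columns(self, session_df):
        model, _ = train_own_data(session_df, seed=2, cfg=FAST)
        out = predict_sequence(model, session_df)
        assert {"pred_A_D", "pred_verg_deg"} <= set(out.columns)
        assert out.loc[~out["discard"], "pred_A_D"].notna().all()


@pytest.fixture(scope="module")
def cohort(scene):
    proto = ProtocolSpec(
        targets=tuple(GazeTarget(1 / a, 0.0315) for a in (4.0, 3.5, 2.5, 1.5, 1.0)),
        dwell_s=0.3,
        discard_window_frames=2,
    )
    subjects = make_cohort(3, 99, anatomy_sd=0.0)
    sessions = [make_session(s, proto, scene) for s in subjects]
    calib = {s.subject_id: make_session(s, proto, scene, rep=1) for s in subjects}
    return pd.concat(sessions, ignore_index=True), calib


class TestLoso:
    def test_fold_per_subject_and_hygiene(self, cohort):
        df, calib = cohort
        folds = train_loso(df, calib, seed=0, cfg=FAST)
        assert [r.subject_id for _, r in folds] == ["S01", "S02", "S03"]
        assert all(r.calibrated for _, r in folds)

    def test_identical_subjects_generalize(self, cohort):
        # zero anatomical variability: a held-out subject is exchangeable
        # with the training subjects, so raw (uncalibrated) held-out error
        # stays close to the own-data error on the same cohort
        df, calib = cohort
        folds = train_loso(df, calib, seed=0, cfg=FAST, calibrate=False)
        loso = np.mean([r.rmse_depth_D for _, r in folds])
        own = np.mean([
            train_own_data(df[df["subject_id"] == sid], seed=0, cfg=FAST)[1].rmse_depth_D
            for sid in ("S01", "S02", "S03")
        ])
        assert loso < own + 0.1

    def test_needs_three_subjects(self, cohort):
        df, calib = cohort
        two = df[df["subject_id"] != "S03"]
        with pytest.raises(ParameterError):
            train_loso(two, calib, seed=0, cfg=FAST)


@pytest.fixture(scope="module")
def fitted(session_df):
    model, _ = train_own_data(session_df, seed=3, cfg=FAST)
    return model


class TestPermutationImportance:
    def test_max_weight_is_one(self, fitted, session_df):
        imp = permutation_importance(fitted, session_df, seed=0)
        assert imp["weight"].max() == pytest.approx(1.0)
        assert (imp["weight"] >= 0).all()

    def test_constant_column_zero_importance(self, session_df):
        df = session_df.copy()
        df["y_P1_px"] = 5.0
        model, _ = train_own_data(df, seed=3, cfg=FAST)
        imp = permutation_importance(model, df, seed=0)
        assert imp.loc["y_P1_px", "weight"] == 0.0
        assert imp.loc["y_P1_px", "constant"]

    def test_pure_noise_input_unimportant(self, session_df, rng):
        df = session_df.copy()
        df["y_P1_px"] = rng.normal(size=len(df))
        model, _ = train_own_data(df, seed=3, cfg=FAST)
        imp = permutation_importance(model, df, seed=0)
        assert imp.loc["y_P1_px", "weight"] < 0.1

    def test_duplicated_input_shares_importance(self, rng):
        # duplicating x_P4 into the pupil slot halves its share of the
        # (minimum-norm) linear solution, so shuffling one copy hurts less
        # than when its duplicate is pure noise; y_P4 dominates both runs so
        # the max-normalisation anchor is unchanged
        from sklearn.linear_model import LinearRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        n = 400
        df = pd.DataFrame({c: rng.normal(size=n) for c in SUBSETS["purkinje+pupil"]})
        df["target_A_D"] = 3.0 * df["y_P4_px"] + 1.0 * df["x_P4_px"]
        df["target_verg_deg"] = 3.0 * df["y_P4_px"] + 1.0 * df["x_P4_px"]
        df[["vis_P1", "vis_P3", "vis_P4"]] = True
        df[["discard", "blink"]] = False
        base = df.copy()
        dup = df.copy()
        dup["x_PC_px"] = dup["x_P4_px"]
        cols = list(SUBSETS["purkinje+pupil"])
        y_cols = ["target_A_D", "target_verg_deg"]
        m_base = make_pipeline(StandardScaler(), LinearRegression()).fit(base[cols], base[y_cols])
        m_dup = make_pipeline(StandardScaler(), LinearRegression()).fit(dup[cols], dup[y_cols])
        i_base = permutation_importance(m_base, base, subset="purkinje+pupil", seed=0)
        i_dup = permutation_importance(m_dup, dup, subset="purkinje+pupil", seed=0)
        assert i_dup.loc["x_P4_px", "weight"] < i_base.loc["x_P4_px", "weight"]
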
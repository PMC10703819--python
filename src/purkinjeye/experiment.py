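"""Experiment orchestration: validated configs, reproducible runs, and the
cohort benchmark (synthetic stand-in for a multi-subject measurement
campaign).

A run simulates a seeded cohort of synthetic subjects under one or two
LED-array configurations ("combined": lateral target offsets, so vergence
and accommodation both vary; "accommodation": targets on the eye axis, no
rotation), then evaluates the analytic estimators, the own-data MLP
protocol and the LOSO+calibration protocol, and writes sequence CSVs,
fit JSONs, an evaluation report and a manifest (config hash, seeds,
version).  All randomness flows from one root seed, split per
stage/subject.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .analytic import accommodation_feature, fit_linear, predict, vergence_feature
from .eye_model import GazeTarget, ParameterError, load_eye_parameters
from .ml import (
    SUBSETS,
    MLPConfig,
    pearson_repeatability,
    permutation_importance,
    rmse,
    train_loso,
    train_own_data,
    usable_rows,
)
from .scene import SceneConfig, load_scene
from .synthetic import ProtocolSpec, make_cohort, make_session, save_sequence

__all__ = [
    "ExperimentConfig",
    "validate_config",
    "run_experiment",
    "cohort_benchmark",
    "analytic_session_rmse",
]


class CohortSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = Field(9, ge=1, le=50)
    anatomy_sd: float = Field(0.03, ge=0.0, le=0.05)
    feature_noise_px: float = Field(0.3, ge=0.0)
    blink_prob: float = Field(0.01, ge=0.0, le=0.2)


class ProtocolModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dwell_s: float = Field(2.0, gt=0)
    frame_rate_hz: float = Field(50.0, gt=0)
    ordering: Literal["sequential", "randomized"] = "sequential"


class MLModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subset: Literal["purkinje", "purkinje+pupil"] = "purkinje"
    leak_free: bool = False
    hidden_options: list[list[int]] | None = None
    batch_options: list[int] | None = None
    epoch_options: list[int] | None = None


class ExperimentConfig(BaseModel):
    """Validated top-level experiment configuration (YAML)."""

    model_config = ConfigDict(extra="forbid")
    schema_id: str = Field("purkinjeye/experiment/v1", alias="schema")
    seed: int = Field(..., ge=0, lt=2**31)  # seeds are mandatory and explicit
    scene_file: str | None = None
    eye_parameter_file: str | None = None
    cohort: CohortSpec = CohortSpec()
    protocol: ProtocolModel = ProtocolModel()
    configurations: list[Literal["combined", "accommodation"]] = Field(
        default_factory=lambda: ["combined", "accommodation"]
    )
    ml: MLModel = MLModel()
    output_dir: str = "purkinjeye-out"

    def mlp_config(self) -> MLPConfig:
        kw: dict = {}
        if self.ml.hidden_options:
            kw["hidden_options"] = tuple(tuple(h) for h in self.ml.hidden_options)
        if self.ml.batch_options:
            kw["batch_options"] = tuple(self.ml.batch_options)
        if self.ml.epoch_options:
            kw["epoch_options"] = tuple(self.ml.epoch_options)
        return MLPConfig(**kw)


def validate_config(path: str) -> ExperimentConfig:
    """Load and validate an experiment YAML; raises with field-level
    messages on any invariant violation.  Never mutates the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    try:
        cfg = ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ParameterError(f"{path}: {msgs}") from exc
    for f in (cfg.scene_file, cfg.eye_parameter_file):
        if f is not None and not Path(f).exists():
            raise ParameterError(f"{path}: referenced file {f!r} does not exist")
    if cfg.scene_file is not None:
        load_scene(cfg.scene_file)
    if cfg.eye_parameter_file is not None:
        load_eye_parameters(cfg.eye_parameter_file)
    return cfg


# ---------------------------------------------------------------------------
# Dataset assembly


def _config_scene(scene: SceneConfig, configuration: str) -> SceneConfig:
    """Derive the per-configuration target array from the base scene."""
    if configuration == "combined":
        return scene
    targets = tuple(GazeTarget(d=t.d, d_target=0.0) for t in scene.target_array)
    return replace(scene, target_array=targets)


def build_cohort_data(
    seed: int,
    scene: SceneConfig,
    configuration: str = "combined",
    n_subjects: int = 9,
    cohort_kwargs: Mapping[str, Any] | None = None,
    protocol_kwargs: Mapping[str, Any] | None = None,
    with_repeat: int = 0,
) -> dict:
    """Simulate all sessions for one configuration.

    Returns a dict with the concatenated cohort sequence, per-subject
    calibration sessions (3.5 D and 1.5 D fixations), and optional repeat
    sessions for the first ``with_repeat`` subjects.
    """
    scn = _config_scene(scene, configuration)
    protocol = ProtocolSpec(targets=tuple(scn.target_array), **(protocol_kwargs or {}))
    cal_targets = tuple(
        t for t in scn.target_array if abs(1.0 / t.d - 3.5) < 1e-9 or abs(1.0 / t.d - 1.5) < 1e-9
    )
    cal_protocol = ProtocolSpec(
        targets=cal_targets,
        dwell_s=protocol.dwell_s,
        frame_rate_hz=protocol.frame_rate_hz,
    )
    subjects = make_cohort(n_subjects, seed, **(cohort_kwargs or {}))
    base = load_eye_parameters()
    sessions, calibrations, repeats = [], {}, {}
    for i, subj in enumerate(subjects):
        sessions.append(make_session(subj, protocol, scn, base_params=base, rep=0))
        calibrations[subj.subject_id] = make_session(
            subj, cal_protocol, scn, base_params=base, rep=1
        )
        if i < with_repeat:
            repeats[subj.subject_id] = make_session(subj, protocol, scn, base_params=base, rep=2)
    return {
        "configuration": configuration,
        "subjects": subjects,
        "protocol": protocol,
        "cohort": pd.concat(sessions, ignore_index=True),
        "calibrations": calibrations,
        "repeats": repeats,
    }


# ---------------------------------------------------------------------------
# Analytic evaluation


def analytic_session_rmse(session: pd.DataFrame) -> dict:
    """Fit the closed-form estimators on one session and score per-target
    mean predictions; returns slopes, intercepts and RMSEs."""
    df = usable_rows(session)
    feats_a = df.apply(accommodation_feature, axis=1).to_numpy()
    feats_v = df.apply(vergence_feature, axis=1).to_numpy()
    model_a = fit_linear(feats_a, df["target_A_D"].to_numpy())
    out = df[["target_A_D", "target_verg_deg"]].copy()
    out["pred_A"] = predict(model_a, feats_a)
    res = {"a_acc": model_a.a, "b_acc": model_a.b}
    if df["target_verg_deg"].nunique() > 1:
        model_v = fit_linear(feats_v, df["target_verg_deg"].to_numpy(), "P3P4")
        out["pred_V"] = predict(model_v, feats_v)
        res.update(a_ver=model_v.a, b_ver=model_v.b)
    per = out.groupby("target_A_D", as_index=False).mean()
    res["depth_rmse_D"] = rmse(per["pred_A"], per["target_A_D"])
    if "pred_V" in out:
        res["angle_rmse_deg"] = rmse(per["pred_V"], per["target_verg_deg"])
    return res


# ---------------------------------------------------------------------------
# Cohort benchmark


def cohort_benchmark(
    seed: int,
    scene: SceneConfig | None = None,
    n_subjects: int = 9,
    configurations: tuple[str, ...] = ("combined", "accommodation"),
    subset: str = "purkinje",
    mlp_cfg: MLPConfig | None = None,
    cohort_kwargs: Mapping[str, Any] | None = None,
    protocol_kwargs: Mapping[str, Any] | None = None,
    n_repeat_subjects: int = 2,
    importance: bool = True,
) -> dict:
    """Run the full synthetic campaign and score every protocol.

    Per configuration: analytic per-subject fits, the own-data MLP
    protocol for every subject, LOSO with two-point calibration, a
    repeatability check on repeated sessions for the first
    ``n_repeat_subjects`` subjects, and permutation importance of the
    inputs.  Returns a nested dict of mean RMSEs and diagnostics.
    """
    scene = scene if scene is not None else load_scene()
    mlp_cfg = mlp_cfg if mlp_cfg is not None else MLPConfig()
    results: dict = {"seed": seed, "n_subjects": n_subjects, "configurations": {}}
    n_target_points = 0
    for ci, conf in enumerate(configurations):
        data = build_cohort_data(
            seed,
            scene,
            conf,
            n_subjects,
            cohort_kwargs=cohort_kwargs,
            protocol_kwargs=protocol_kwargs,
            with_repeat=n_repeat_subjects,
        )
        cohort = data["cohort"]
        n_target_points += len(data["protocol"].targets)
        cres: dict = {}

        # analytic estimators, per subject
        per_subj = [
            analytic_session_rmse(cohort[cohort["subject_id"] == s.subject_id])
            for s in data["subjects"]
        ]
        cres["analytic_depth_rmse_D"] = float(np.mean([r["depth_rmse_D"] for r in per_subj]))
        if "angle_rmse_deg" in per_subj[0]:
            cres["analytic_angle_rmse_deg"] = float(
                np.mean([r["angle_rmse_deg"] for r in per_subj])
            )

        # own-data MLP protocol
        own_models, own_reports = {}, []
        for si, s in enumerate(data["subjects"]):
            sdf = cohort[cohort["subject_id"] == s.subject_id]
            mseed = np.random.SeedSequence([61, seed, ci, si]).generate_state(1)[0]
            model, report = train_own_data(sdf, subset, int(mseed), mlp_cfg)
            own_models[s.subject_id] = (model, int(mseed))
            own_reports.append(report)
        cres["own_depth_rmse_D"] = float(np.mean([r.rmse_depth_D for r in own_reports]))
        cres["own_max_depth_rmse_D"] = float(np.max([r.rmse_depth_D for r in own_reports]))
        if conf == "combined":
            cres["own_angle_rmse_deg"] = float(
                np.mean([r.rmse_angle_deg for r in own_reports])
            )

        # LOSO + two-point calibration (needs >= 3 subjects)
        loso = []
        if n_subjects >= 3:
            loso = train_loso(
                cohort,
                data["calibrations"],
                subset,
                int(np.random.SeedSequence([67, seed, ci]).generate_state(1)[0]),
                mlp_cfg,
            )
        if loso:
            cres["loso_depth_rmse_D"] = float(np.mean([r.rmse_depth_D for _, r in loso]))
            cres["loso_max_depth_rmse_D"] = float(np.max([r.rmse_depth_D for _, r in loso]))
            if conf == "combined":
                cres["loso_angle_rmse_deg"] = float(
                    np.mean([r.rmse_angle_deg for _, r in loso])
                )

        # repeatability: re-run own-data prediction on a repeat session
        reps = []
        for sid, repeat_df in data["repeats"].items():
            model, mseed = own_models[sid]
            sdf = usable_rows(cohort[cohort["subject_id"] == sid], subset)
            rdf = usable_rows(repeat_df, subset)
            n = min(len(sdf), len(rdf))
            cols = list(SUBSETS[subset])
            p1 = model.predict(sdf[cols].to_numpy()[:n])[:, 0]
            p2 = model.predict(rdf[cols].to_numpy()[:n])[:, 0]
            reps.append(pearson_repeatability(p1, p2))
        if reps:
            cres["repeatability_pearson_r"] = float(np.mean(reps))

        # permutation importance of the pooled cohort under the first
        # subject's model (configuration-specific weighting)
        if importance:
            first = data["subjects"][0].subject_id
            model, mseed = own_models[first]
            imp = permutation_importance(model, cohort, subset, seed=seed)
            cres["permutation_importance"] = {
                k: float(v) for k, v in imp["weight"].items()
            }

        results["configurations"][conf] = cres

    confs = results["configurations"]
    results["n_target_test_points"] = n_target_points
    results["own_depth_rmse_D"] = float(np.mean([c["own_depth_rmse_D"] for c in confs.values()]))
    if all("loso_depth_rmse_D" in c for c in confs.values()):
        results["loso_depth_rmse_D"] = float(
            np.mean([c["loso_depth_rmse_D"] for c in confs.values()])
        )
    results["analytic_depth_rmse_D"] = float(
        np.mean([c["analytic_depth_rmse_D"] for c in confs.values()])
    )
    return results


# ---------------------------------------------------------------------------
# File-producing experiment runner


def _hash_config(cfg: ExperimentConfig) -> str:
    payload = json.dumps(cfg.model_dump(by_alias=True), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig, out_dir: str | None = None) -> dict:
    """Execute a configured experiment and write the artifact bundle.

    Writes per-configuration cohort CSVs, the evaluation report JSON and a
    manifest; returns the manifest.  Reruns with the same config produce
    byte-identical outputs (timestamps excluded by design: none are
    written).
    """
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = load_scene(cfg.scene_file)
    protocol_kwargs = cfg.protocol.model_dump()
    results = cohort_benchmark(
        cfg.seed,
        scene,
        n_subjects=cfg.cohort.n,
        configurations=tuple(cfg.configurations),
        subset=cfg.ml.subset,
        mlp_cfg=cfg.mlp_config(),
        cohort_kwargs={
            "anatomy_sd": cfg.cohort.anatomy_sd,
            "feature_noise_px": cfg.cohort.feature_noise_px,
            "blink_prob": cfg.cohort.blink_prob,
        },
        protocol_kwargs=protocol_kwargs,
    )
    written = []
    for conf in cfg.configurations:
        data = build_cohort_data(
            cfg.seed,
            scene,
            conf,
            cfg.cohort.n,
            cohort_kwargs={
                "anatomy_sd": cfg.cohort.anatomy_sd,
                "feature_noise_px": cfg.cohort.feature_noise_px,
                "blink_prob": cfg.cohort.blink_prob,
            },
            protocol_kwargs=protocol_kwargs,
        )
        path = out / f"cohort_{conf}.csv"
        save_sequence(data["cohort"], str(path))
        written.append(path.name)
    report_path = out / "evaluation.json"
    report_path.write_text(json.dumps(results, indent=2, sort_keys=True))
    written.append(report_path.name)
    manifest = {
        "config_hash": _hash_config(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "outputs": written,
        "config": cfg.model_dump(by_alias=True),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
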
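"""End-to-end analysis: tracking -> metrics -> statistics -> classification.

``run_pipeline`` consumes a cohort manifest of recorded (or rendered) trials;
``cohort_metrics`` summarizes simulated trials directly from their ground
truth, which is the fast path used for simulation studies.  Per-trial
failures are quarantined, not fatal; every output embeds the master seed and
a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as wio
from .classify import assemble_features, cross_validate, train_svm
from .geometry import VesselPhantom, build_phantom
from .metrics import (
    CollisionParams,
    FEATURE_ORDER,
    metric_vector,
    speed_profile,
)
from .simulate import SimulatedTrial, trial_observations
from .stats import build_significance_tables
from .tracking import TrackingConfig, polyline_from_mask, track_sequence

__all__ = ["PipelineConfig", "PipelineResult", "cohort_metrics", "run_pipeline"]

META_COLUMNS = ("trial_id", "group", "surgeon_id", "task", "repetition")


@dataclass
class PipelineConfig:
    geometry: dict | None = None
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    collision: CollisionParams = field(default_factory=CollisionParams)
    alpha: float = 0.05
    svm_c: float = 0.8
    svm_gamma: float = 20.0
    train_fraction: float = 0.65
    cv_folds: int = 5
    trim_time: bool = False

    def hash(self) -> str:
        doc = {
            "geometry": self.geometry,
            "tracking": asdict(self.tracking),
            "collision": asdict(self.collision),
            "alpha": self.alpha,
            "svm_c": self.svm_c,
            "svm_gamma": self.svm_gamma,
            "train_fraction": self.train_fraction,
            "cv_folds": self.cv_folds,
            "trim_time": self.trim_time,
        }
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    within_table: object
    between_table: object
    classifier_report: object
    cv_accuracy: tuple | None
    quarantined: list
    seed: int
    config_hash: str


def trial_metric_vector(trial: SimulatedTrial, phantom: VesselPhantom, **kwargs):
    """Metric vector of a simulated trial computed from its ground truth."""
    return metric_vector(
        trajectory=trial.truth_tip_path,
        force=trial.force,
        phantom=phantom,
        task=trial.meta["task"],
        fps=trial.meta["fps"],
        observations=trial_observations(trial),
        speed=trial.truth_speed,
        **kwargs,
    )


def cohort_metrics(trials, phantom: VesselPhantom, **kwargs) -> pd.DataFrame:
    """One metric row per simulated trial (ground-truth streams)."""
    rows = []
    for i, trial in enumerate(trials):
        mv = trial_metric_vector(trial, phantom, **kwargs)
        row = {
            "trial_id": trial.meta.get("trial_id", f"trial_{i:03d}"),
            "group": trial.meta["group"],
            "surgeon_id": trial.meta.get("surgeon_id"),
            "task": trial.meta["task"],
            "repetition": trial.meta.get("repetition"),
        }
        row.update(mv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _analyze_table(df: pd.DataFrame, config: PipelineConfig, seed: int):
    within = between = report = cv = None
    if df["vascular_difficulty"].nunique() == 2 and df["group"].nunique() == 2:
        within, between = build_significance_tables(df, alpha=config.alpha)
    if df["group"].nunique() == 2 and df["group"].value_counts().min() >= 4:
        features = assemble_features(df)
        _, report = train_svm(
            features, C=config.svm_c, gamma=config.svm_gamma,
            train_fraction=config.train_fraction, seed=seed,
        )
        k = min(config.cv_folds, int(df["group"].value_counts().min()))
        cv = cross_validate(features, k=k, C=config.svm_c, gamma=config.svm_gamma,
                            seed=seed)
    return within, between, report, cv


def run_pipeline(
    manifest_path,
    out_dir,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full assessment pipeline over a cohort manifest.

    Each trial is tracked, summarized into the nine metrics, then the cohort
    is analyzed (significance tables, SVM report).  A trial that fails at any
    stage is quarantined with its error and the pipeline continues.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, fps = wio.load_manifest(manifest_path)
    phantom = build_phantom(config.geometry)

    rows, quarantined = [], []
    for rec in records:
        try:
            frames = wio.read_frames(rec.frames_path, fps=fps)
            observations, traj = track_sequence(
                frames, config.tracking, seed_hint=rec.seed_hint
            )
            for obs in observations:
                if obs.wire_mask is not None:
                    obs.wire_polyline = polyline_from_mask(obs.wire_mask, obs.tip)
            force = wio.read_force_csv(rec.force_path)
            speed = None
            if rec.speed_path:
                log = pd.read_csv(rec.speed_path)
                speed = speed_profile(controller=log["v"].to_numpy())
            mv = metric_vector(
                trajectory=traj,
                force=force,
                phantom=phantom,
                task=rec.task,
                fps=frames.fps,
                observations=observations,
                speed=speed,
                collision_params=config.collision,
                trim_time=config.trim_time,
            )
        except Exception as exc:  # quarantine, keep going
            quarantined.append({"trial_id": rec.trial_id, "error": str(exc)})
            continue
        row = {
            "trial_id": rec.trial_id,
            "group": rec.group,
            "surgeon_id": rec.surgeon_id,
            "task": rec.task,
            "repetition": rec.repetition,
        }
        row.update(mv.as_dict())
        rows.append(row)

    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_ORDER))
    stamp = {"seed": int(seed), "config_hash": config.hash()}
    wio.write_metrics_csv(df, out_dir / "metrics.csv", provenance=stamp)

    within = between = report = cv = None
    if len(df) >= 8:
        within, between, report, cv = _analyze_table(df, config, seed)
    if within is not None:
        within.p_values.to_csv(out_dir / "within_group_pvalues.csv")
        between.p_values.to_csv(out_dir / "between_group_pvalues.csv")
        with open(out_dir / "significance.json", "w") as fh:
            json.dump({"within_group": within.to_json_dict(),
                       "between_group": between.to_json_dict(), **stamp}, fh, indent=2)
    if report is not None:
        doc = asdict(report)
        doc["confusion"] = {f"{a}->{b}": v for (a, b), v in report.confusion.items()}
        doc.update(stamp)
        if cv is not None:
            doc["cv_mean_accuracy"], doc["cv_fold_accuracies"] = cv
        with open(out_dir / "classifier_report.json", "w") as fh:
            json.dump(doc, fh, indent=2)
    with open(out_dir / "quarantine.json", "w") as fh:
        json.dump({"quarantined": quarantined, **stamp}, fh, indent=2)

    return PipelineResult(
        metrics=df,
        within_table=within,
        between_table=between,
        classifier_report=report,
        cv_accuracy=cv,
        quarantined=quarantined,
        seed=int(seed),
        config_hash=config.hash(),
    )
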
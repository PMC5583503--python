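"""End-to-end workflow: simulate -> preprocess -> segment -> label ->
features -> balance -> train -> predict -> evaluate.

`run_end_to_end` mirrors the intended field workflow on synthetic data:
a training session pair (one per technique class) builds a personalized
classifier, which then scores a held-out session pair; every
intermediate artifact is written to disk with provenance, and the final
report carries the held-out confusion counts and metrics.  Fully
deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import TechniqueForest, balance_training_set
from .evaluate import confusion, metrics
from .features import FEATURE_NAMES, build_feature_matrix
from .preprocess import build_signal_set
from .segment import segment_repetitions
from .store import SessionDatabase, save_database, save_model
from .streams import write_stream
from .synth import SynthConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_end_to_end", "version_and_provenance", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and artifacts so far."""

    def __init__(self, stage: str, artifacts: dict[str, str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}; artifacts so far: {artifacts}")
        self.stage = stage
        self.artifacts = artifacts


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end run, serializable to YAML."""

    # signal processing
    fs: float = 51.2
    fc: float = 20.0
    filter_order: int = 8
    beta: float = 0.1
    # segmentation
    channel: str | None = None
    min_prominence: float = 0.3
    min_separation: float = 1.0
    # simulation (study conditions: 20 acceptable + 20 aberrant per exercise)
    exercise: str = "squat"
    n_reps_train: int = 20       # per class
    n_reps_holdout: int = 10     # per class
    deviation: str = "frontal_wobble"
    deviation_magnitude: float = 0.8
    noise_sd_acc: float = 0.02
    noise_sd_gyro: float = 1.0
    noise_sd_mag: float = 0.01
    # classification
    n_trees: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps_train < 2 or self.n_reps_holdout < 1:
            raise ValueError("need >= 2 training and >= 1 held-out repetitions per class")
        SynthConfig(  # defers range checks to the synth module
            n_reps=self.n_reps_train,
            deviation=self.deviation,
            deviation_magnitude=self.deviation_magnitude,
            noise_sd_acc=self.noise_sd_acc,
            noise_sd_gyro=self.noise_sd_gyro,
            noise_sd_mag=self.noise_sd_mag,
            fs=self.fs,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sha256(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def version_and_provenance(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Provenance record stamped into every output artifact."""
    record = {"tool": "repform", "version": __version__}
    if config is not None:
        record["config_sha256"] = config.sha256()
        record["seed"] = config.seed if seed is None else seed
    elif seed is not None:
        record["seed"] = seed
    return record


def _synth_config(cfg: PipelineConfig, n_reps: int, aberrant: bool, seed: int, tag: str) -> SynthConfig:
    return SynthConfig(
        n_reps=n_reps,
        deviation=cfg.deviation if aberrant else "none",
        deviation_magnitude=cfg.deviation_magnitude if aberrant else 0.0,
        noise_sd_acc=cfg.noise_sd_acc,
        noise_sd_gyro=cfg.noise_sd_gyro,
        noise_sd_mag=cfg.noise_sd_mag,
        fs=cfg.fs,
        seed=seed & 0x7FFFFFFF,
        session_id=tag,
        exercise=cfg.exercise,
    )


def run_end_to_end(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full workflow; returns (and optionally writes) the report.

    Sessions are simulated per class for training and hold-out, labels
    are taken from the simulation ground truth (standing in for the
    exercise professional), and the held-out sessions are never seen at
    training time.  When ``outdir`` is given, every intermediate
    artifact (streams, signal sets, database, feature table, model,
    predictions, report) is written beneath it.
    """
    config.validate()
    provenance = version_and_provenance(config)
    artifacts: dict[str, str] = {}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        artifacts["config"] = str(outdir / "config.yaml")

    def _write_stream(stream, name):
        if outdir is None:
            return
        path = write_stream(
            stream, outdir / f"{name}.csv",
            header_comments={k: str(v) for k, v in provenance.items()},
        )
        artifacts[name] = str(path)

    # --- simulate ------------------------------------------------------
    stage = "simulate"
    try:
        plan = {
            "train-acceptable": (config.n_reps_train, False, config.seed * 4 + 0),
            "train-aberrant": (config.n_reps_train, True, config.seed * 4 + 1),
            "holdout-acceptable": (config.n_reps_holdout, False, config.seed * 4 + 2),
            "holdout-aberrant": (config.n_reps_holdout, True, config.seed * 4 + 3),
        }
        sessions = {}
        for tag, (n, aberrant, seed) in plan.items():
            stream, truth = generate_session(_synth_config(config, n, aberrant, seed, tag))
            sessions[tag] = (stream, truth)
            _write_stream(stream, f"stream_{tag}")
    except Exception as exc:
        raise StageError(stage, artifacts, exc) from exc

    # --- preprocess + segment + label ---------------------------------
    db = SessionDatabase()
    db.add_label(config.exercise, "Aberrant")
    warnings_list: list[str] = []
    try:
        stage = "preprocess"
        signal_sets = {
            tag: build_signal_set(stream, beta=config.beta, fc=config.fc, order=config.filter_order)
            for tag, (stream, _) in sessions.items()
        }
        stage = "segment"
        for tag, signals in signal_sets.items():
            truth = sessions[tag][1]
            reps = segment_repetitions(
                signals,
                channel=config.channel,
                min_prominence=config.min_prominence,
                min_separation=config.min_separation,
            )
            if len(reps) != truth.n_reps:
                warnings_list.append(
                    f"{tag}: segmented {len(reps)} repetitions, ground truth {truth.n_reps}"
                )
            # ground truth stands in for the professional's labels
            label = truth.labels[0]
            for rep in reps:
                rep.label = label
            db.add_session(signals, reps, labeled=True)
        if outdir is not None:
            artifacts["database"] = str(save_database(db, outdir / "database"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, artifacts, exc) from exc

    # --- features / balance / train ------------------------------------
    try:
        stage = "features"
        train_keys = [k for k in db.keys() if k[0].startswith("train-")]
        matrix, labels, keys = build_feature_matrix(db, config.exercise)
        key_index = {k: i for i, k in enumerate(keys)}
        train_idx = [key_index[k] for k in train_keys]
        holdout_idx = [key_index[k] for k in db.keys() if k[0].startswith("holdout-")]
        if outdir is not None:
            table = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
            table.insert(0, "label", labels)
            table.insert(0, "rep_key", [str(k) for k in keys])
            with open(outdir / "features.csv", "w") as handle:
                for k, v in provenance.items():
                    handle.write(f"# {k}: {v}\n")
                table.to_csv(handle, index=False)
            artifacts["features"] = str(outdir / "features.csv")
        stage = "balance"
        train_labels = [labels[i] for i in train_idx]
        keep = balance_training_set(train_labels, seed=config.seed)
        balanced_idx = [train_idx[i] for i in keep]
        stage = "train"
        per_class = min(
            pd.Series([labels[i] for i in balanced_idx]).value_counts()
        )
        if per_class < 5:
            warnings_list.append(
                f"small training sample: only {per_class} repetitions per class"
            )
        model = TechniqueForest(
            endog=[labels[i] for i in balanced_idx],
            exog=matrix[balanced_idx],
            exercise=config.exercise,
            training_keys=[keys[i] for i in balanced_idx],
            n_trees=config.n_trees,
        )
        results = model.fit(seed=config.seed)
        if outdir is not None:
            artifacts["model"] = str(save_model(results, outdir / "model.joblib"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, artifacts, exc) from exc

    # --- predict + evaluate --------------------------------------------
    try:
        stage = "predict"
        pred_labels, votes = results.predict(matrix[holdout_idx])
        truth_labels = [labels[i] for i in holdout_idx]
        if outdir is not None:
            pred_df = pd.DataFrame(
                {
                    "rep_key": [str(keys[i]) for i in holdout_idx],
                    "truth": truth_labels,
                    "predicted": pred_labels,
                    "vote_fraction": votes,
                }
            )
            with open(outdir / "predictions.csv", "w") as handle:
                for k, v in provenance.items():
                    handle.write(f"# {k}: {v}\n")
                pred_df.to_csv(handle, index=False)
            artifacts["predictions"] = str(outdir / "predictions.csv")
        stage = "evaluate"
        counts = confusion(truth_labels, list(pred_labels))
        report_metrics = metrics(counts)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, artifacts, exc) from exc

    report = {
        "provenance": provenance,
        "exercise": config.exercise,
        "n_train_per_class": config.n_reps_train,
        "n_holdout_per_class": config.n_reps_holdout,
        "n_balanced_training_reps": len(balanced_idx),
        "oob_accuracy": results.oob_accuracy,
        "confusion": {"tp": counts.tp, "fn": counts.fn, "tn": counts.tn, "fp": counts.fp},
        "holdout_accuracy_pct": report_metrics.accuracy,
        "holdout_sensitivity_pct": report_metrics.sensitivity,
        "holdout_specificity_pct": report_metrics.specificity,
        "warnings": warnings_list,
        "artifacts": artifacts,
    }
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
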
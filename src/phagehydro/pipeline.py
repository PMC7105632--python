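"""The two-stage cascade: enzyme vs non-enzyme, then hydrolase vs other enzyme.

Stage 1 classifies every query as enzyme or non-enzyme on its scheme's
ANOVA/IFS-selected feature subset (the full 714-feature concatenation by
default).  Stage 2, trained independently on enzyme-only data with the
GGDC+PseAAC scheme, is applied only to stage-1 positives; non-enzymes get
a ``not-applicable`` stage-2 call.  Each stage is a fitted scaler+SVM
pipeline plus its selected feature-name list, independently serializable
to a human-auditable directory.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from . import __version__
from .encoders import encode_combined, encode_sequence, scheme_dimension, _scheme_blocks
from .evaluation import (
    ClassifierSpec,
    EvalReport,
    build_estimator,
    decision_scores,
    grid_search_hyperparameters,
    jackknife_evaluate,
)
from .exceptions import ConfigError, LengthError, PhageHydroError
from .features import FeatureMatrix
from .selection import IFSResult, anova_f, incremental_feature_selection
from .seq_io import Dataset

__all__ = [
    "CascadeConfig",
    "TrainedStage",
    "CascadeModel",
    "CascadePrediction",
    "train_cascade",
    "predict_cascade",
    "save_cascade",
    "load_cascade",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Training configuration for both stages.

    ``pinned_sizes`` bypasses IFS with fixed subset sizes (stage1, stage2);
    ``grid_search=False`` skips hyperparameter search and uses the spec's
    defaults.  ``cv`` is 'loo' (jackknife) or an integer fold count, used
    for both the grid search and IFS.
    """

    scheme1: str = "all"
    scheme2: str = "ggdc+pseaac"
    classifier: str = "svm-rbf"
    cv: object = "loo"
    ifs_stride: int = 1
    pinned_sizes: tuple[int | None, int | None] = (None, None)
    grid_search: bool = True
    c_grid: tuple[float, ...] | None = None
    gamma_grid: tuple[float, ...] | None = None
    g: int = 2
    lam: int = 15
    seed: int = 0
    evaluate_stages: bool = True


@dataclass
class TrainedStage:
    """One fitted stage: scheme, selected features, spec and model."""

    scheme: str
    selected_features: list[str]
    spec: ClassifierSpec
    model: Pipeline
    ifs: IFSResult | None = None
    report: EvalReport | None = None
    g: int = 2
    lam: int = 15

    def __post_init__(self) -> None:
        universe_dim = scheme_dimension(self.scheme, g=self.g, lam=self.lam)
        if len(self.selected_features) > universe_dim:
            raise PhageHydroError(
                f"stage selects {len(self.selected_features)} features but scheme "
                f"{self.scheme!r} has only {universe_dim}"
            )
        allowed = set(_scheme_blocks(self.scheme))
        bad = [n for n in self.selected_features if n.split("|", 1)[0] not in allowed]
        if bad:
            raise PhageHydroError(
                f"selected features outside scheme {self.scheme!r}: {bad[:3]}"
            )

    def encode_one(self, sequence: str, seq_id: str = "?") -> np.ndarray:
        fv = encode_sequence(sequence, scheme=self.scheme, g=self.g, lam=self.lam, seq_id=seq_id)
        index = {n: i for i, n in enumerate(fv.names)}
        return fv.values[[index[n] for n in self.selected_features]]

    def scaling_stats(self) -> pd.DataFrame | None:
        """Per-feature training min/max, when the model scales its input."""
        if "scale" not in self.model.named_steps:
            return None
        scaler = self.model.named_steps["scale"]
        return pd.DataFrame(
            {
                "feature": self.selected_features,
                "data_min": scaler.data_min_,
                "data_max": scaler.data_max_,
            }
        )


@dataclass
class CascadeModel:
    stage1: TrainedStage
    stage2: TrainedStage
    metadata: dict = field(default_factory=dict)


@dataclass
class CascadePrediction:
    """Per-sample cascade calls; ``stage2_call`` is 'not-applicable' iff the
    sample was called non-enzyme at stage 1."""

    sample_id: str
    stage1_call: str = ""
    stage1_score: float = float("nan")
    stage2_call: str = ""
    stage2_score: float = float("nan")
    error: str | None = None


def _train_stage(dataset: Dataset, scheme: str, config: CascadeConfig, pinned: int | None) -> TrainedStage:
    dataset.require_labels()
    matrix = encode_combined(dataset, scheme=scheme, g=config.g, lam=config.lam)
    if config.classifier == "svm-rbf" and config.grid_search:
        kwargs = {}
        if config.c_grid is not None:
            kwargs["c_grid"] = config.c_grid
        if config.gamma_grid is not None:
            kwargs["gamma_grid"] = config.gamma_grid
        spec = grid_search_hyperparameters(matrix, cv=config.cv, seed=config.seed, **kwargs)
    else:
        spec = ClassifierSpec(config.classifier, {}, seed=config.seed)
    ifs: IFSResult | None = None
    if pinned is not None:
        if not (1 <= pinned <= matrix.n_features):
            raise ConfigError(f"pinned subset size {pinned} outside 1..{matrix.n_features}")
        selected = anova_f(matrix).top(pinned)
    else:
        ifs = incremental_feature_selection(matrix, spec, cv=config.cv, stride=config.ifs_stride)
        selected = ifs.selected_features
    sub = matrix.subset(selected)
    model = build_estimator(spec)
    model.fit(sub.values, matrix.labels)
    report = None
    if config.evaluate_stages:
        sub_labelled = FeatureMatrix(sub.sample_ids, sub.names, sub.values, matrix.labels)
        report = jackknife_evaluate(sub_labelled, spec)
    return TrainedStage(scheme, list(selected), spec, model, ifs=ifs, report=report,
                        g=config.g, lam=config.lam)


def train_cascade(set1: Dataset, set2: Dataset, config: CascadeConfig | None = None) -> CascadeModel:
    """Train both stages independently on their own labelled datasets.

    Stage 2 trains only on stage-2-labelled (enzyme) data; the cascade is
    composed at prediction time, not during training.
    """
    config = config or CascadeConfig()
    stage1 = _train_stage(set1, config.scheme1, config, config.pinned_sizes[0])
    stage2 = _train_stage(set2, config.scheme2, config, config.pinned_sizes[1])
    metadata = {
        "version": __version__,
        "seed": config.seed,
        "cv": str(config.cv),
        "n_set1": len(set1),
        "n_set2": len(set2),
        "scheme1": config.scheme1,
        "scheme2": config.scheme2,
    }
    return CascadeModel(stage1, stage2, metadata)


def predict_cascade(model: CascadeModel, dataset: Dataset) -> list[CascadePrediction]:
    """Apply the cascade; stage 2 runs only on stage-1 positives.

    A sequence too short for an encoder yields a per-sample error entry
    while the remaining samples proceed.
    """
    out: list[CascadePrediction] = []
    for rec in dataset:
        pred = CascadePrediction(sample_id=rec.id)
        try:
            x1 = model.stage1.encode_one(rec.sequence, rec.id).reshape(1, -1)
        except LengthError as exc:
            pred.error = str(exc)
            pred.stage1_call = "error"
            pred.stage2_call = "error"
            out.append(pred)
            continue
        call1 = int(model.stage1.model.predict(x1)[0])
        pred.stage1_score = float(decision_scores(model.stage1.model, x1)[0])
        pred.stage1_call = "enzyme" if call1 == 1 else "non-enzyme"
        if call1 != 1:
            pred.stage2_call = "not-applicable"
            out.append(pred)
            continue
        try:
            x2 = model.stage2.encode_one(rec.sequence, rec.id).reshape(1, -1)
        except LengthError as exc:
            pred.error = str(exc)
            pred.stage2_call = "error"
            out.append(pred)
            continue
        call2 = int(model.stage2.model.predict(x2)[0])
        pred.stage2_score = float(decision_scores(model.stage2.model, x2)[0])
        pred.stage2_call = "hydrolase" if call2 == 1 else "non-hydrolase"
        out.append(pred)
    return out


# --------------------------------------------------------------------------
# persistence: a directory with auditable text artifacts + the fitted state


def _save_stage(stage: TrainedStage, stage_dir: Path) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    cfg = {
        "scheme": stage.scheme,
        "g": stage.g,
        "lam": stage.lam,
        "classifier": stage.spec.kind,
        "hyperparameters": stage.spec.hyperparameters,
        "seed": stage.spec.seed,
    }
    (stage_dir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    (stage_dir / "features.txt").write_text("\n".join(stage.selected_features) + "\n")
    stats = stage.scaling_stats()
    if stats is not None:
        stats.to_csv(stage_dir / "scaling.tsv", sep="\t", index=False)
    joblib.dump(stage.model, stage_dir / "model.joblib")


def _load_stage(stage_dir: Path) -> TrainedStage:
    cfg = json.loads((stage_dir / "config.json").read_text())
    features = (stage_dir / "features.txt").read_text().splitlines()
    model = joblib.load(stage_dir / "model.joblib")
    spec = ClassifierSpec(cfg["classifier"], dict(cfg["hyperparameters"]), seed=cfg["seed"])
    # TrainedStage.__post_init__ re-asserts feature-universe membership here
    return TrainedStage(cfg["scheme"], features, spec, model, g=cfg["g"], lam=cfg["lam"])


def save_cascade(model: CascadeModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "meta.json").write_text(json.dumps(model.metadata, indent=2) + "\n")
    _save_stage(model.stage1, directory / "stage1")
    _save_stage(model.stage2, directory / "stage2")


def load_cascade(directory) -> CascadeModel:
    directory = Path(directory)
    if not (directory / "meta.json").exists():
        raise PhageHydroError(f"{directory}: not a cascade model directory")
    metadata = json.loads((directory / "meta.json").read_text())
    return CascadeModel(
        _load_stage(directory / "stage1"),
        _load_stage(directory / "stage2"),
        metadata,
    )
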
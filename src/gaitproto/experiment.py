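"""End-to-end open-set recognition experiments over repeated splits.

One *repetition*: partition subjects 20/10/10, train the encoder-decoder
on the training group, embed everything, fit a centroid and a one-class
SVM per known subject from the n reserved shots, then score the known and
unknown test sets.  Metrics are averaged over repetitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import (LRPConfig, common_map, make_occlusion_plan,
                          perturbation_curve)
from .config import ExperimentConfig
from .encoder import TrainedModel, train
from .gait_signal import StepDataset
from .recognizer import (Centroid, MetricsReport, MetricsSummary, OSVMModel,
                         Split, compute_centroid, evaluate, fit_osvm,
                         split_dataset)


@dataclass
class Pipeline:
    """A trained recognition pipeline with its boundaries held fixed."""

    model: TrainedModel
    centroids: list[Centroid]
    models: dict[int, OSVMModel]
    tau: float
    split: Split | None = None

    def embed(self, steps: np.ndarray) -> np.ndarray:
        return self.model.embed(steps)

    def evaluate(self, known_emb: dict[int, np.ndarray],
                 unknown_emb: np.ndarray) -> MetricsReport:
        return evaluate(known_emb, unknown_emb, self.centroids, self.models,
                        self.tau)


def fit_pipeline(model: TrainedModel, shots: dict[int, np.ndarray],
                 gamma: float, nu: float, tau: float,
                 split: Split | None = None) -> Pipeline:
    """Centroids + one-class boundaries from each known subject's shots."""
    centroids, models = [], {}
    for a, steps in shots.items():
        emb = model.embed(steps)
        centroids.append(compute_centroid(emb, a))
        models[a] = fit_osvm(emb, gamma, nu, subject=a)
    return Pipeline(model, centroids, models, tau, split)


def run_repetition(dataset: StepDataset, config: ExperimentConfig,
                   repetition: int,
                   model: TrainedModel | None = None) -> tuple[MetricsReport, Pipeline]:
    """One repetition; pass ``model`` to reuse an already-trained encoder."""
    split = split_dataset(dataset, config.split, repetition)
    if model is None:
        enc_cfg = replace(config.encoder,
                          seed=(config.encoder.seed + repetition) % 2**31)
        model = train(split.train, enc_cfg)
    pipeline = fit_pipeline(model, split.shots, config.gamma, config.nu,
                            config.tau, split)
    known_emb = {a: model.embed(v) for a, v in split.known_test.items()}
    unknown = np.concatenate(list(split.unknown_test.values()), axis=0)
    report = pipeline.evaluate(known_emb, model.embed(unknown))
    return report, pipeline


@dataclass
class ExperimentResult:
    summary: MetricsSummary
    pipelines: list[Pipeline] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() | {"repetition": i}
                for i, r in enumerate(self.summary.reports)]
        df = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_row = df.mean(numeric_only=True).to_dict() | {"repetition": "mean"}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "metrics.csv", index=False)
        payload = {
            "repetitions": [r.as_dict() for r in self.summary.reports],
            "mean": self.summary.mean(),
            "splits": [p.split.manifest() for p in self.pipelines if p.split],
        }
        (directory / "metrics.json").write_text(json.dumps(payload, indent=2))


def run_experiment(dataset: StepDataset, config: ExperimentConfig,
                   keep_pipelines: int = 1,
                   model: TrainedModel | None = None) -> ExperimentResult:
    """All repetitions of the split protocol; keeps the first few pipelines."""
    summary = MetricsSummary()
    pipelines: list[Pipeline] = []
    for rep in range(config.split.repetitions):
        report, pipeline = run_repetition(dataset, config, rep, model=model)
        summary.reports.append(report)
        if rep < keep_pipelines:
            pipelines.append(pipeline)
    return ExperimentResult(summary, pipelines)


def run_perturbation(pipeline: Pipeline, config: ExperimentConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Common-map region perturbation for a trained pipeline.

    The common attribution map is averaged over a per-subject subsample of
    the training split (``config.common_map_steps_per_subject`` steps
    each), then the test sets are re-scored with quintiles O1..O5 and a
    size-matched random baseline occluded.
    """
    if pipeline.split is None:
        raise ValueError("pipeline carries no split; cannot run perturbation")
    rng = rng or np.random.default_rng(config.seed)
    k = config.common_map_steps_per_subject
    subsample = {a: v[:k] for a, v in pipeline.split.train.items()}
    cmap = common_map(pipeline.model.encoder, subsample, config.method,
                      LRPConfig(config.epsilon))
    plan = make_occlusion_plan(cmap)
    results = perturbation_curve(plan, pipeline.split.known_test,
                                 pipeline.split.unknown_test, pipeline, rng)
    rows = []
    for name, report in results.items():
        rows.append({"occlusion": name, "baseline": name == "random"}
                    | report.as_dict())
    return pd.DataFrame(rows)
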
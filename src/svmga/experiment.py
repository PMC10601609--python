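"""End-to-end experiment orchestration.

An experiment = generate (or load) a cohort, split it, then run the MI
filter sweep and/or the embedded GA, writing a deterministic artifact
layout: cohort CSV + metadata, one sweep CSV per benchmark classifier, a GA
trajectory CSV, a best-subset JSON and a summary JSON.  All randomness
flows from the named seeds in the config, so rerunning a stored config
reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .datasets import (
    DEFAULT_TRAIN_COUNTS,
    FeatureDataset,
    GeneratorConfig,
    generate_cohort,
    read_dataset,
    stratified_split,
    write_dataset,
)
from .ga import GAConfig, GAResult, run_ga
from .mi_filter import sequential_elimination_sweep
from .svm import BenchmarkClassifierSpec

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "summarize"]

logger = logging.getLogger(__name__)

_CLASSIFIER_KINDS = ("simple_tree", "rbf_svm", "linear_svm", "knn")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    train_counts: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_TRAIN_COUNTS))
    split_seed: int = 0
    filter_classifiers: tuple[str, ...] = _CLASSIFIER_KINDS
    filter_bins: int = 8
    filter_step: int = 1
    run_filter: bool = True
    run_ga_stage: bool = True
    data_path: str | None = None  # load instead of generate when set
    output_dir: str = "experiment_out"

    def __post_init__(self) -> None:
        problems = []
        for kind in self.filter_classifiers:
            if kind not in _CLASSIFIER_KINDS:
                problems.append(f"unknown filter classifier {kind!r}")
        if self.filter_bins < 2:
            problems.append("filter_bins must be >= 2")
        if self.filter_step < 1:
            problems.append("filter_step must be >= 1")
        if problems:
            raise ValueError("invalid experiment config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ExperimentConfig":
        kwargs = dict(raw)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "ga" in kwargs:
            kwargs["ga"] = GAConfig(**kwargs["ga"])
        if "train_counts" in kwargs:
            kwargs["train_counts"] = {int(k): int(v) for k, v in kwargs["train_counts"].items()}
        if "filter_classifiers" in kwargs:
            kwargs["filter_classifiers"] = tuple(kwargs["filter_classifiers"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["train_counts"] = {str(k): v for k, v in self.train_counts.items()}
        out["filter_classifiers"] = list(self.filter_classifiers)
        return out


@dataclass
class ExperimentReport:
    """Paths and headline numbers of a completed experiment."""

    config: ExperimentConfig
    output_dir: Path
    summary: dict[str, Any]
    sweep_paths: dict[str, Path] = field(default_factory=dict)
    trajectory_path: Path | None = None
    best_subset_path: Path | None = None


def _ga_summary(result: GAResult, d: int) -> dict[str, Any]:
    last = result.trajectory[-1]
    convergence_epoch = next(
        rec.epoch for rec in result.trajectory if rec.best_ff <= result.best_fitness.ff_total
    )
    return {
        "d": d,
        "m_best": result.best_subset.m,
        "best_ff": result.best_fitness.ff_total,
        "ff_breakdown": {
            "ff1": result.best_fitness.ff1,
            "ff2": result.best_fitness.ff2,
            "ff3": result.best_fitness.ff3,
        },
        "train_acc": last.train_acc,
        "test_acc": last.test_acc,
        "overall_acc": last.overall_acc,
        "epochs_run": last.epoch,
        "convergence_epoch": convergence_epoch,
        "n_fitness_evaluations": result.n_evaluations,
    }


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the configured stages and write the artifact layout."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.data_path is not None:
        dataset: FeatureDataset = read_dataset(config.data_path)
    else:
        dataset = generate_cohort(config.generator)
        write_dataset(dataset, out / "cohort.csv", config=config.generator)
    split = stratified_split(dataset, config.train_counts, seed=config.split_seed)

    summary: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
        "n_train": len(split.train_indices),
        "n_test": len(split.test_indices),
    }
    report = ExperimentReport(config=config, output_dir=out, summary=summary)

    if config.run_filter:
        for kind in config.filter_classifiers:
            logger.info("filter sweep: %s", kind)
            curve = sequential_elimination_sweep(
                split,
                BenchmarkClassifierSpec(kind=kind),
                step=config.filter_step,
                n_bins=config.filter_bins,
            )
            path = out / f"sweep_{kind}.csv"
            curve.to_frame().to_csv(path, index=False)
            report.sweep_paths[kind] = path
        summary["filter_sweeps"] = {k: str(p) for k, p in report.sweep_paths.items()}

    if config.run_ga_stage:
        logger.info(
            "GA stage: %d chromosomes x %d generations",
            config.ga.n_chromosomes,
            config.ga.max_generations,
        )
        result = run_ga(split, config.ga)
        traj_path = out / "ga_trajectory.csv"
        with traj_path.open("w") as fh:
            fh.write("epoch,best_ff,train_acc,test_acc,overall_acc,m_best\n")
            for rec in result.trajectory:
                fh.write(
                    f"{rec.epoch},{rec.best_ff:.10g},{rec.train_acc:.10g},"
                    f"{rec.test_acc:.10g},{rec.overall_acc:.10g},{rec.m_best}\n"
                )
        report.trajectory_path = traj_path

        subset_path = out / "best_subset.json"
        names = [dataset.feature_names[i] for i in result.best_subset.indices]
        subset_path.write_text(
            json.dumps(
                {
                    "mask": result.best_subset.mask.astype(int).tolist(),
                    "feature_names": names,
                    "fitness": dataclasses.asdict(result.best_fitness),
                },
                indent=2,
            )
        )
        report.best_subset_path = subset_path
        summary["ga"] = _ga_summary(result, dataset.n_features)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report


def summarize(report: ExperimentReport) -> str:
    """Human-readable recap of an experiment report."""
    lines = [f"svmga {report.summary['version']} experiment in {report.output_dir}"]
    lines.append(
        f"cohort: {report.summary['n_samples']} samples x {report.summary['n_features']} features "
        f"(train {report.summary['n_train']}, test {report.summary['n_test']})"
    )
    ga = report.summary.get("ga")
    if ga is None:
        lines.append("no GA stage run")
    else:
        lines.append(f"dimensionality reduced {ga['d']} -> {ga['m_best']}")
        lines.append(
            f"final model: train {ga['train_acc']:.3f}, test {ga['test_acc']:.3f}, "
            f"overall {ga['overall_acc']:.3f} accuracy"
        )
        lines.append(
            f"best fitness {ga['best_ff']:.4f} reached at epoch {ga['convergence_epoch']} "
            f"of {ga['epochs_run']}"
        )
    for kind, path in report.sweep_paths.items():
        lines.append(f"filter sweep ({kind}): {path}")
    return "\n".join(lines)
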
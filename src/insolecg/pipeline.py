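"""File-based pipeline: staged execution with on-disk artifacts.

Each stage reads the previous stage's files from the run directory and
writes its own, so runs are inspectable and partially repeatable:

  simulate -> preprocess -> phases -> features -> augment -> train
  -> predict -> evaluate -> report

The resolved configuration and a content hash are written next to the
outputs of every run; re-running with the same configuration and seed
reproduces identical metric files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .augmentation import AugmentationConfig
from .preprocessing import PreprocessingConfig
from .protocol import (ProtocolConfig, SubjectData, cv_fold_subjects,
                       group_pv_analysis, prepare_subjects, run_protocol)
from .synthetic import GeneratorConfig, generate_cohort, read_trials, \
    write_trials

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "phases", "features", "augment",
          "train", "predict", "evaluate", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Master configuration of a pipeline run."""

    seed: int = 0
    outdir: str = "runs/default"
    fold: int = 0
    methods: tuple[str, ...] = ("proposed",)
    protocol: ProtocolConfig = ProtocolConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        proto = raw.pop("protocol", {})
        nested = {}
        for key, sub_cls in (("generator", GeneratorConfig),
                             ("preprocessing", PreprocessingConfig),
                             ("augmentation", AugmentationConfig)):
            if key in proto:
                nested[key] = sub_cls(**proto.pop(key))
        if "feature_counts_grid" in proto:
            proto["feature_counts_grid"] = tuple(proto["feature_counts_grid"])
        protocol = ProtocolConfig(**proto, **nested)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(protocol=protocol, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name!r}: run the {stage!r} stage first")
    return path


class PipelineRun:
    """Stage executor bound to one run directory."""

    def __init__(self, config: PipelineConfig, need_models: bool = True):
        self.config = config
        self.need_models = need_models
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._subjects: list[SubjectData] | None = None
        self._results: dict | None = None
        (self.outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))
        (self.outdir / "config.hash").write_text(config.content_hash())

    # -- stages ----------------------------------------------------------
    def simulate(self) -> None:
        p = self.config.protocol
        trials = generate_cohort(p.n_young, p.n_old, p.trials_per_subject,
                                 self.config.seed, p.generator)
        write_trials(trials, self.outdir / "trials")
        logger.info("simulate: wrote %d trials", len(trials))

    def _load_subjects(self) -> list[SubjectData]:
        if self._subjects is None:
            trials_dir = _require(self.outdir / "trials" / "manifest.json",
                                  "simulate").parent
            trials = read_trials(trials_dir)
            self._subjects = prepare_subjects(trials, self.config.protocol)
        return self._subjects

    def preprocess(self) -> None:
        subjects = self._load_subjects()
        meta = []
        arrays = {}
        for s, sub in enumerate(subjects):
            meta.append({"subject_id": sub.subject_id, "group": sub.group,
                         "n_trials": len(sub.samples)})
            for t, (sample, feat) in enumerate(zip(sub.samples, sub.features)):
                arrays[f"pressures_{s}_{t}"] = sample.cycle.pressures
                arrays[f"cg_{s}_{t}"] = sample.cg.cg
                arrays[f"cg_mm_{s}_{t}"] = sample.cg.cg_mm
                arrays[f"labels_{s}_{t}"] = sample.labels
        np.savez_compressed(self.outdir / "processed.npz", **arrays)
        (self.outdir / "subjects.json").write_text(json.dumps(meta, indent=1))
        logger.info("preprocess: %d subjects", len(subjects))

    def _run_protocol(self) -> dict:
        if self._results is None:
            _require(self.outdir / "subjects.json", "preprocess")
            subjects = self._load_subjects()
            p = self.config.protocol
            tr, va, te = cv_fold_subjects(
                p.n_young, p.n_old, self.config.fold,
                p.n_val_per_group, p.n_test_per_group)
            methods = self.config.methods if self.need_models else ()
            self._results = run_protocol(subjects, tr, va, te, p,
                                         self.config.seed, methods=methods)
        return self._results

    def phases(self) -> None:
        res = self._run_protocol()
        res["phase_classifier"].save(self.outdir / "phase_classifier.pkl")
        rep = dict(res["phase_report"])
        rep["confusion_matrix"] = rep["confusion_matrix"].tolist()
        (self.outdir / "phase_report.json").write_text(
            json.dumps(rep, indent=1))

    def features(self) -> None:
        res = self._run_protocol()
        res["selection"].to_json(self.outdir / "selection.json")
        lines = ["phase,k,rrmse_pct"]
        for phase, curve in res["selection"].error_curves.items():
            for k, err in sorted(curve.items()):
                lines.append(f"{phase},{k},{err!r}")
        (self.outdir / "feature_count_curves.csv").write_text(
            "\n".join(lines) + "\n")

    def augment(self) -> None:
        res = self._run_protocol()
        (self.outdir / "augmentation.json").write_text(json.dumps(
            {"n_training_frames": res["n_training_frames"],
             "folds": 4 if self.config.protocol.augmentation.enabled else 1}))

    def train(self) -> None:
        res = self._run_protocol()
        for method, entry in res["methods"].items():
            entry["model"].save(self.outdir / f"model_{method}")

    def predict(self) -> None:
        res = self._run_protocol()
        for method, entry in res["methods"].items():
            arrays = {f"pred_mm_{i}": p.cg_mm
                      for i, p in enumerate(entry["predictions"])}
            np.savez(self.outdir / f"predictions_{method}.npz", **arrays)

    def evaluate(self) -> None:
        res = self._run_protocol()
        payload = {m: e["report"].to_dict()
                   for m, e in res["methods"].items()}
        payload["failed_methods"] = res["failed_methods"]
        (self.outdir / "evaluation.json").write_text(
            json.dumps(payload, indent=1))
        rows = ["method,group,axis,r_mean,r_min,r_max,"
                "rmse_mm_mean,rmse_mm_sd,rrmse_pct_mean,rrmse_pct_sd"]
        for m, e in res["methods"].items():
            for group, axes in e["report"].to_dict().items():
                for axis, v in axes.items():
                    rows.append(
                        f"{m},{group},{axis},{v['r_mean']:.6g},"
                        f"{v['r_min']:.6g},{v['r_max']:.6g},"
                        f"{v['rmse_mm_mean']:.6g},{v['rmse_mm_sd']:.6g},"
                        f"{v['rrmse_pct_mean']:.6g},{v['rrmse_pct_sd']:.6g}")
        (self.outdir / "evaluation.csv").write_text("\n".join(rows) + "\n")
        # group PV analysis of reference and (if present) proposed output
        ref = {g: [] for g in ("young", "old")}
        for sample, g in zip(res["test_samples"], res["test_groups"]):
            ref[g].append(sample.cg.cg_mm)
        analysis = {"reference": group_pv_analysis(ref)}
        if "proposed" in res["methods"]:
            pred = {g: [] for g in ("young", "old")}
            for p, g in zip(res["methods"]["proposed"]["predictions"],
                            res["test_groups"]):
                pred[g].append(p.cg_mm)
            analysis["proposed"] = group_pv_analysis(pred)
        (self.outdir / "group_analysis.json").write_text(
            json.dumps(analysis, indent=1))

    def report(self) -> None:
        parts = {}
        for name in ("phase_report", "evaluation", "group_analysis",
                     "augmentation"):
            path = self.outdir / f"{name}.json"
            if path.exists():
                parts[name] = json.loads(path.read_text())
        (self.outdir / "report.json").write_text(json.dumps(parts, indent=1))


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in protocol order; returns the run dir."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    need_models = bool(set(stages) & {"train", "predict", "evaluate",
                                      "report"})
    run = PipelineRun(config, need_models=need_models)
    for stage in STAGES:
        if stage in stages:
            logger.info("stage: %s", stage)
            getattr(run, stage)()
    return run.outdir
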
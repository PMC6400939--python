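"""End-to-end orchestration: simulate -> features -> classify -> stats -> optimize.

One YAML config and one master seed drive every stage; each stage's
randomness comes from a named substream of the master seed, and every output
file is SHA-256-hashed into ``manifest.json`` so reruns are verifiably
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .classification import KernelConfig, run_task
from .features import FEATURE_NAMES, extract_features
from .imaging import CalibrationReference, calibrate_frame, stitch_biopsy
from .specificity import run_optimization_experiment
from .stats import fig3_analysis
from .synthetic import (
    Biopsy,
    ClassParams,
    GeneratorConfig,
    generate_cohort,
    generate_paired_agent_biopsies,
)

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"simulate": 1, "features": 2, "classify": 3, "stats": 4, "optimize": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Single config object for a full pipeline run."""

    out_dir: str = "run_output"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    counts: dict = field(default_factory=lambda: {"tumor": 27, "benign": 10, "mammoplasty": 6})
    n_grid: int = 1000
    top_p: float = 0.01
    cv_folds: int = 10
    kernel: KernelConfig = field(default_factory=KernelConfig)
    tasks: list = field(default_factory=lambda: ["tumor_vs_mammoplasty", "tumor_vs_benign"])
    # optimisation arms: label -> specificity factor of the binding probe
    arms: dict = field(default_factory=lambda: {"incubation=1min": 3.0, "incubation=5min": 3.0, "incubation=10min": 1.5})
    n_pairs: int = 4
    run_optimize: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.get("generator", {})
        if isinstance(gen, dict):
            gen = dict(gen)
            if "class_params" in gen:
                gen["class_params"] = {
                    k: ClassParams(**v) if isinstance(v, dict) else v
                    for k, v in gen["class_params"].items()
                }
            if isinstance(gen.get("annotation_params"), dict):
                from .synthetic import AnnotationParams

                def _ann(v):
                    if not isinstance(v, dict):
                        return v
                    return AnnotationParams(**{
                        k2: tuple(v2) if k2.endswith("_range") else v2
                        for k2, v2 in v.items()
                    })

                gen["annotation_params"] = {
                    k: _ann(v) for k, v in gen["annotation_params"].items()
                }
            d["generator"] = GeneratorConfig(**gen)
        kern = d.get("kernel", {})
        if isinstance(kern, dict):
            d["kernel"] = KernelConfig(**kern)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def stage_simulate(config: RunConfig) -> list[Biopsy]:
    out = Path(config.out_dir) / "images"
    cohort = generate_cohort(config.generator, config.counts,
                             seed=stage_seed(config.seed, "simulate"))
    hio.write_cohort(cohort, out)
    return cohort


def stitch_cohort(biopsies: list[Biopsy], slide_mean: float = 1.0):
    """Calibrate each frame against its session reference, then stitch."""
    stitched = []
    for b in biopsies:
        refs = {
            f.session_id: CalibrationReference(
                session_id=f.session_id, slide_mean=slide_mean,
                reference_gain=1.0, reference_exposure=1.0,
            )
            for f in b.frames
        }
        frames = [calibrate_frame(f, refs[f.session_id]) for f in b.frames]
        stitched.append(stitch_biopsy(frames, biopsy_id=b.biopsy_id))
    return stitched


def compute_features_table(
    biopsies: list[Biopsy], n_grid: int = 1000, top_p: float = 0.01
) -> pd.DataFrame:
    """One row of the 12 predictors per biopsy, in canonical column order."""
    stitched = stitch_cohort(biopsies)
    rows = []
    for b, s in zip(biopsies, stitched):
        fv = extract_features(s, n_grid=n_grid, top_p=top_p)
        row = {"biopsy_id": b.biopsy_id, "tissue_class": b.tissue_class,
               "subtype": b.subtype}
        row.update({n: getattr(fv, n) for n in FEATURE_NAMES})
        row["fits_converged"] = fv.fits_converged
        rows.append(row)
    return pd.DataFrame(rows)


def stage_features(config: RunConfig) -> pd.DataFrame:
    out = Path(config.out_dir)
    biopsies = hio.read_cohort(out / "images")
    table = compute_features_table(biopsies, n_grid=config.n_grid, top_p=config.top_p)
    table.to_csv(out / "features.csv", index=False)
    return table


def stage_classify(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    table = pd.read_csv(out / "features.csv")
    seed = stage_seed(config.seed, "classify")
    reports = {}
    for task in config.tasks:
        rep = run_task(table, task, k=config.cv_folds,
                       kernel_config=config.kernel, seed=seed)
        reports[task] = rep
        _write_json({
            "task": task,
            "best_set": list(rep.selection.best_set),
            "best_auc": rep.selection.best_auc,
            "auc": rep.roc.auc,
            "sensitivity": rep.operating_point.sensitivity,
            "specificity": rep.operating_point.specificity,
            "threshold": rep.operating_point.threshold,
            "youden_j": rep.operating_point.youden_j,
            "block_aucs": rep.block_aucs,
            "cv_seed": rep.selection.cv_seed,
            "candidate_aucs": [
                {"features": list(f), "auc": a} for f, a in rep.selection.candidate_sets
            ],
            "scores": {bid: s for bid, s in zip(rep.biopsy_ids, rep.scores)},
        }, out / f"report_{task}.json")
        pd.DataFrame({
            "threshold": rep.roc.thresholds,
            "sensitivity": rep.roc.sens,
            "specificity": rep.roc.spec,
        }).to_csv(out / f"roc_{task}.csv", index=False)
    return reports


def stage_stats(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    features = pd.read_csv(out / "features.csv")
    annotations = pd.read_csv(out / "images" / "cohort.csv")
    report = fig3_analysis(features, annotations)
    tukey = report.get("group_comparison", {}).get("tukey")
    if tukey is not None:
        tukey.to_csv(out / "pairwise_tukey.csv", index=False)
    serialisable = {
        k: v for k, v in report.items() if k != "group_comparison"
    }
    if "group_comparison" in report:
        serialisable["group_comparison"] = {
            "F": report["group_comparison"]["F"],
            "p": report["group_comparison"]["p"],
        }
    _write_json(serialisable, out / "stats_report.json")
    return report


def stage_optimize(config: RunConfig):
    out = Path(config.out_dir)
    seed = stage_seed(config.seed, "optimize")
    arm_seeds = np.random.SeedSequence([seed]).generate_state(len(config.arms))
    arms = {
        label: generate_paired_agent_biopsies(
            config.generator, factor, config.n_pairs,
            seed=int(s % (2**31)),
        )
        for (label, factor), s in zip(config.arms.items(), arm_seeds)
    }
    results, ks_table, ranking = run_optimization_experiment(
        arms, n_grid=config.n_grid, seed=seed
    )
    rows = []
    for label, arm in results.items():
        for g, m, s in zip(arm.grid, arm.mean_frac, arm.sem_frac):
            rows.append({"arm": label, "grid": g, "mean": m, "sem": s})
    pd.DataFrame(rows).to_csv(out / "arm_curves.csv", index=False)
    ks_table.to_csv(out / "ks_table.csv", index=False)
    _write_json({"ranking": ranking,
                 "mean_ratios": {l: results[l].mean_ratio for l in results}},
                out / "optimization_report.json")
    return results, ks_table, ranking


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every requested stage in dependency order and write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "features", "classify", "stats"]
    if config.run_optimize:
        stages.append("optimize")
    log = []
    for stage in stages:
        t0 = time.perf_counter()
        {"simulate": stage_simulate, "features": stage_features,
         "classify": stage_classify, "stats": stage_stats,
         "optimize": stage_optimize}[stage](config)
        log.append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3),
                    "seed": stage_seed(config.seed, stage)})
        logger.info("stage %s done in %.2fs", stage, log[-1]["seconds"])

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": log,
        "files": {str(p.relative_to(out)): _hash_file(p) for p in files},
    }
    # stage wall times vary between runs; hashes must not
    manifest_for_hash = dict(manifest)
    manifest_for_hash["stages"] = [
        {k: v for k, v in s.items() if k != "seconds"} for s in log
    ]
    _write_json(manifest_for_hash, out / "manifest.json")
    return manifest
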
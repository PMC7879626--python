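"""End-to-end orchestration: simulate → cohort → features → train → evaluate.

One master seed deterministically derives a per-stage seed (fixed offsets,
recorded in the run manifest), so re-running with the same config
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortConfig, build_cohort, write_cohort
from .data_model import StudyDataset, read_dataset, write_dataset
from .definitions import builtin_definitions, save_definitions
from .features import build_features, screen_features
from .metrics import evaluate_all, format_report
from .model import calibration_slope, score as score_patients, train as train_model
from .simulate import default_config as default_sim_config
from .simulate import simulate as run_simulation
from .simulate import write_truth

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "cohort": 1,
    "train": 2,
    "evaluate": 3,
}


@dataclass
class RunConfig:
    out_dir: str = "run"
    master_seed: int = 0
    n_train: int = 20_000
    n_test: int = 20_000
    control_ratio: float = 233.0
    top_k_features: int = 500
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    model_params: dict = field(default_factory=dict)
    cv_folds: int = 10
    chart_review_error: float = 0.0

    def stage_seed(self, stage: str) -> int:
        return self.master_seed + STAGE_SEED_OFFSETS[stage]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline into ``config.out_dir``; returns the directory.

    Outputs: data/ (train, test CSVs, truth.csv), cohort.csv,
    features.csv, model.json, importance.tsv, definitions.yaml,
    results.tsv, results_formatted.tsv and manifest.json.
    """
    out = Path(config.out_dir)
    (out / "data" / "train").mkdir(parents=True, exist_ok=True)
    (out / "data" / "test").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {}, "hashes": {}}

    sim_cfg = default_sim_config(
        n_train=config.n_train,
        n_test=config.n_test,
        chart_review_error=config.chart_review_error,
        seed=config.stage_seed("simulate"),
    )
    defs = builtin_definitions(sim_cfg.basal_insulin_codes)
    sim_cfg.require_codes(defs)  # fail before any compute if codes missing

    def stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s …", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 2)}
        return result

    def _simulate():
        train_ds, test_ds, truth = run_simulation(sim_cfg)
        write_dataset(train_ds, out / "data" / "train")
        write_dataset(test_ds, out / "data" / "test")
        write_truth(truth, out / "data" / "truth.csv")
        return train_ds, test_ds, truth

    train_ds, test_ds, truth = stage("simulate", _simulate)
    manifest["seeds"]["simulate"] = config.stage_seed("simulate")

    def _cohort():
        cc = CohortConfig(
            control_ratio=config.control_ratio,
            chart_review_error=config.chart_review_error,
            insulin_codes=sim_cfg.insulin_codes,
        )
        c = build_cohort(
            train_ds, truth=truth, config=cc, seed=config.stage_seed("cohort")
        )
        write_cohort(c, out / "cohort.csv")
        return c

    cohort = stage("cohort", _cohort)
    manifest["seeds"]["cohort"] = config.stage_seed("cohort")

    def _features_and_train():
        labeled = cohort[cohort["status"].isin(("case", "control"))]
        sub = StudyDataset(
            patients=train_ds.patients[
                train_ds.patients["patient_id"].isin(labeled["patient_id"])
            ].reset_index(drop=True),
            events=train_ds.events[
                train_ds.events["patient_id"].isin(labeled["patient_id"])
            ].reset_index(drop=True),
            labs=train_ds.labs,
            flags=train_ds.flags,
            period="training",
        )
        fm = build_features(sub)
        labels = (
            labeled.set_index("patient_id")["status"] == "case"
        ).astype(int)
        fm = screen_features(fm, labels, k=config.top_k_features)
        fm.matrix.to_csv(out / "features.csv")
        bundle = train_model(
            fm,
            labels,
            seed=config.stage_seed("train"),
            params=config.model_params,
            cv_folds=config.cv_folds,
        )
        bundle.save(out / "model.json")
        bundle.importance().to_csv(out / "importance.tsv", sep="\t", index=False)
        logger.info("mean 10-fold CV AUC: %.3f", bundle.mean_cv_auc)
        return bundle

    bundle = stage("train", _features_and_train)
    manifest["seeds"]["train"] = config.stage_seed("train")
    manifest["cv_auc"] = bundle.cv_auc

    def _evaluate():
        test_fm = build_features(test_ds)
        scores = score_patients(bundle, test_fm)
        t = truth.set_index("patient_id")["latent_t1d"]
        slope = calibration_slope(scores, t.loc[scores["patient_id"]])
        manifest["calibration_slope"] = round(slope, 3)
        if not 0.8 <= slope <= 1.2:
            logger.warning(
                "calibration slope %.2f outside [0.8, 1.2]; probabilistic "
                "indexes may be biased", slope,
            )
        save_definitions(defs, out / "definitions.yaml")
        table = evaluate_all(
            scores,
            defs,
            test_ds,
            n_reps=config.bootstrap_reps,
            level=config.ci_level,
            seed=config.stage_seed("evaluate"),
        )
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        format_report(table).to_csv(
            out / "results_formatted.tsv", sep="\t", index=False
        )
        return table

    stage("evaluate", _evaluate)
    manifest["seeds"]["evaluate"] = config.stage_seed("evaluate")

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["hashes"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
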
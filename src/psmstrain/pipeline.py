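"""End-to-end analysis runner: features -> comparisons -> agreement ->
diagnostics/reclassification -> time-dependent survival.

A single mandatory seed fans out to per-stage seeds through a fixed
``SeedSequence`` derivation, so a full run is reproducible while stages stay
independently re-runnable. Every stage writes its artifact into the output
directory; any stage failure aborts the run with a stage-named error and
removes the partial outputs of this run.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    compare_metrics_by_grade,
    diag_metrics,
    fleiss_kappa_ci,
    reclassification_matrix,
)
from .features import (
    DIFFERENCE_COLUMNS,
    TTP_MINUS_AVC_COLUMNS,
    FeatureConfig,
    HeuristicThresholds,
    features_frame,
)
from .strain_io import cohort_frame, read_cohort_table, read_strain_table
from .survival import cohort_intervals, fit_td_cox, intervals_frame
from .types import RaterGrades

logger = logging.getLogger(__name__)

_STAGES = ("features", "compare", "agreement", "diagnostics", "survival")


@dataclass(frozen=True)
class RunConfig:
    """Inputs, options and the mandatory seed for a full analysis run."""

    strain_path: Optional[str]
    cohort_path: str
    out_dir: str
    seed: int
    grading: str = "grade_combined"
    raters_path: Optional[str] = None
    pauc_lo: float = 33.0
    pauc_hi: float = 66.0
    n_boot: int = 2000
    thresholds: HeuristicThresholds = field(default_factory=HeuristicThresholds)

    def __post_init__(self):
        if not self.pauc_lo < self.pauc_hi:
            raise ValueError("pauc window requires lo < hi")
        if self.grading not in ("grade_2d", "grade_combined"):
            raise ValueError(f"unknown grading {self.grading!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw) if thr is None else cls(
            **raw, thresholds=HeuristicThresholds.from_dict(thr)
        )
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2**31)."""
    idx = _STAGES.index(stage) if stage in _STAGES else len(_STAGES)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the map of artifact names to paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, Path] = {}
    run_log: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "grading": config.grading,
        "n_boot": config.n_boot,
    }

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        artifacts[name] = path
        return path

    current_stage = "setup"
    try:
        records = read_cohort_table(config.cohort_path)
        cohort_df = cohort_frame(records)
        run_log["n_exams"] = len(records)
        run_log["n_patients"] = cohort_df["patient_id"].nunique()

        current_stage = "features"
        feat_df = None
        if config.strain_path is not None:
            exams = read_strain_table(config.strain_path)
            fcfg = FeatureConfig(pauc_lo=config.pauc_lo, pauc_hi=config.pauc_hi)
            feat_df = features_frame(exams, fcfg)
            feat_df.to_csv(emit("features", out_dir / "features.csv"), index=False)
            run_log["n_strain_exams"] = len(exams)

        current_stage = "compare"
        if feat_df is not None:
            merged = feat_df.merge(
                cohort_df[["exam_id", config.grading]], on="exam_id", how="inner"
            )
            metrics = [
                c for c in DIFFERENCE_COLUMNS + TTP_MINUS_AVC_COLUMNS
                if c in merged.columns
            ]
            results = compare_metrics_by_grade(merged, metrics, grade_col=config.grading)
            rows = []
            for r in results:
                row = {"metric": r.metric, "p": r.p_raw, "p_adjusted": r.p_adjusted}
                for g, med in r.median_per_grade.items():
                    lo, hi = r.iqr_per_grade[g]
                    row[f"median_grade{g}"] = med
                    row[f"q25_grade{g}"] = lo
                    row[f"q75_grade{g}"] = hi
                rows.append(row)
            pd.DataFrame(rows).to_csv(
                emit("compare", out_dir / "grade_comparison.csv"), index=False
            )

        current_stage = "agreement"
        if config.raters_path is not None:
            rdf = pd.read_csv(config.raters_path)
            rater_cols = [c for c in rdf.columns if c.startswith("rater")]
            ratings = [
                RaterGrades(
                    exam_id=str(row["exam_id"]),
                    grades=tuple(int(row[c]) for c in rater_cols),
                )
                for _, row in rdf.iterrows()
            ]
        else:
            both = cohort_df.dropna(subset=["grade_2d", "grade_combined"])
            ratings = [
                RaterGrades(
                    exam_id=str(r.exam_id),
                    grades=(int(r.grade_2d), int(r.grade_combined)),
                )
                for r in both.itertuples()
            ]
        kappa = fleiss_kappa_ci(
            ratings, n_boot=config.n_boot, seed=stage_seed(config.seed, "agreement")
        )
        _dump_json(
            {
                "kappa": kappa.kappa,
                "ci_low": kappa.ci_low,
                "ci_high": kappa.ci_high,
                "n_exams": kappa.n_exams,
                "n_boot": kappa.n_boot,
                "seed": kappa.seed,
            },
            emit("agreement", out_dir / "agreement.json"),
        )

        current_stage = "diagnostics"
        diag_df = cohort_df.dropna(subset=[config.grading, "rv_lv_ratio"])
        grade = diag_df[config.grading].astype(int)
        diag_payload: dict[str, object] = {
            "n_complete": int(len(diag_df)),
            "n_missing": int(len(cohort_df) - len(diag_df)),
        }
        for name, test, cond in (
            ("grade2_predicts_severe_dilatation", grade == 2, diag_df["rv_lv_ratio"] >= 1.0),
            ("psm_predicts_dilatation", grade >= 1, diag_df["rv_lv_ratio"] >= 0.6),
        ):
            d = diag_metrics(test.to_numpy(), cond.to_numpy())
            diag_payload[name] = {
                "sensitivity": d.sensitivity,
                "sens_ci": list(d.sens_ci),
                "specificity": d.specificity,
                "spec_ci": list(d.spec_ci),
                "counts": {"tp": d.tp, "fp": d.fp, "fn": d.fn, "tn": d.tn},
            }
        _dump_json(diag_payload, emit("diagnostics", out_dir / "diagnostics.json"))
        matrix, n_excluded = reclassification_matrix(records)
        matrix.to_csv(emit("reclassification", out_dir / "reclassification.csv"))
        run_log["reclassification_excluded"] = n_excluded

        current_stage = "survival"
        intervals = cohort_intervals(records, grading=config.grading)
        intervals_frame(intervals).to_csv(
            emit("intervals", out_dir / "intervals.csv"), index=False
        )
        cox = fit_td_cox(intervals)
        _dump_json(cox.to_dict(), emit("survival", out_dir / "survival.json"))
        run_log["n_events"] = cox.n_events
        run_log["n_survival_patients"] = cox.n_patients

        current_stage = "run-log"
        _dump_json(run_log, emit("run_log", out_dir / "run_log.json"))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"stage '{current_stage}' failed: {exc}") from exc
    return artifacts
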
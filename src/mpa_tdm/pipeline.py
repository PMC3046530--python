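"""End-to-end pipeline: cohort -> NCA -> outcomes -> statistics -> ROC report.

Stages run in a fixed order and each writes its artifact before the next
starts; on a stage failure the completed artifacts are retained and the
MANIFEST records which stages finished. ``run_metadata.json`` echoes the
full configuration (including the simulator seed when the cohort was
simulated), the package version, the NCA method and the quantile
convention, which is enough to replay the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .errors import PipelineError
from .eligibility import classify_outcomes
from .io import read_cohort, render_comparison_report, write_cohort
from .model import Cohort
from .nca import pk_params_frame, pk_summary
from .roc import HIGHER, LOWER, auc, empirical_roc, hanley_mcneil, optimal_threshold
from .simulate import SimConfig, simulate_cohort
from .stats import compare_groups, correlation_frame, correlations

log = logging.getLogger("mpa_tdm.pipeline")

#: default ROC predictors with their orientation (positive class = flare)
DEFAULT_PREDICTORS: dict[str, str] = {
    "mpa_auc_0_12": LOWER,
    "mpa_c12h": LOWER,
    "ratio_c12h": HIGHER,
}

_PK_COLUMNS = {"mpa_auc_0_12", "mpa_cmax", "mpa_tmax", "mpa_c12h",
               "mpag_auc_0_12", "mpag_cmax", "mpag_tmax", "mpag_c12h",
               "ratio_auc", "ratio_c12h"}


@dataclass
class PipelineConfig:
    output_dir: str
    input_dir: Optional[str] = None       # directory with the four cohort CSVs
    sim: Optional[SimConfig] = None       # or simulate a cohort instead
    nca_method: str = "linlog"
    predictors: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTORS))
    alpha: float = 0.05

    def validate(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise PipelineError("config: exactly one of input_dir / sim is required")
        unknown = set(self.predictors) - _PK_COLUMNS
        if unknown:
            raise PipelineError(f"config: unknown ROC predictor(s) {sorted(unknown)}")
        for direction in self.predictors.values():
            if direction not in (LOWER, HIGHER):
                raise PipelineError(f"config: unknown direction {direction!r}")
        if self.nca_method not in ("linlog", "linear"):
            raise PipelineError(f"config: unknown NCA method {self.nca_method!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; returns artifact name -> path. Raises PipelineError."""
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: list[str] = []
    manifest_path = os.path.join(out, "MANIFEST")

    def done(stage: str) -> None:
        manifest.append(stage)
        with open(manifest_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(manifest) + "\n")

    def run_stage(stage, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        done(stage)
        return result

    def load() -> Cohort:
        if config.sim is not None:
            cohort = simulate_cohort(config.sim)
            write_cohort(cohort, os.path.join(out, "cohort"))
            log.info("simulated cohort: %d patients", len(cohort.patients))
            return cohort
        cohort = read_cohort(
            os.path.join(config.input_dir, "patients.csv"),
            os.path.join(config.input_dir, "samples.csv"),
            os.path.join(config.input_dir, "visits.csv"),
            os.path.join(config.input_dir, "outcomes.csv"))
        log.info("read cohort: %d patients", len(cohort.patients))
        return cohort

    cohort = run_stage("load_cohort", load)

    def outcomes_stage():
        discontinued = []
        if cohort.outcomes is not None:
            discontinued = [o.patient_id for o in cohort.outcomes
                            if o.label == "excluded"]
        labels = classify_outcomes(cohort, discontinued)
        df = pd.DataFrame([{
            "patient_id": o.patient_id, "label": o.label,
            "flare_month": o.flare_month, "exclusion_reason": o.exclusion_reason,
        } for o in labels])
        path = os.path.join(out, "outcomes.csv")
        df.to_csv(path, index=False)
        artifacts["outcomes"] = path
        log.info("outcomes: %d success / %d failure / %d excluded",
                 sum(o.label == "success" for o in labels),
                 sum(o.label == "failure" for o in labels),
                 sum(o.label == "excluded" for o in labels))
        return labels

    labels = run_stage("classify_outcomes", outcomes_stage)
    analyzed = [o.patient_id for o in labels if o.label != "excluded"]

    def nca_stage():
        params = pk_summary(cohort, config.nca_method, patient_ids=analyzed)
        frame = pk_params_frame(params)
        path = os.path.join(out, "pk_params.csv")
        frame.to_csv(path, index=False, float_format="%.12g")
        artifacts["pk_params"] = path
        log.info("nca: %d patients -> %s", len(frame), path)
        return frame

    pk = run_stage("nca", nca_stage)

    def stats_stage():
        comparison = compare_groups(cohort, pk, labels)
        path = os.path.join(out, "comparison.csv")
        render_comparison_report(comparison, path)
        artifacts["comparison"] = path
        corr = correlation_frame(correlations(cohort, pk, labels))
        cpath = os.path.join(out, "correlations.csv")
        corr.to_csv(cpath, index=False, float_format="%.6g")
        artifacts["correlations"] = cpath
        log.info("stats: %d comparison rows, %d correlations",
                 len(comparison), len(corr))

    run_stage("statistics", stats_stage)

    def roc_stage():
        merged = pk.set_index("patient_id")
        label_by_id = {o.patient_id: o.label for o in labels}
        roc_rows, thr_rows = [], []
        for predictor, direction in config.predictors.items():
            sub = merged.loc[[i for i in analyzed if i in merged.index], predictor]
            sub = sub.dropna()
            y = [1 if label_by_id[i] == "failure" else 0 for i in sub.index]
            scores = sub.to_numpy(float)
            curve = empirical_roc(scores, y, direction, predictor)
            res = hanley_mcneil(auc(curve), curve.n_pos, curve.n_neg,
                                config.alpha)
            roc_rows.append({"predictor": predictor, "direction": direction,
                             "auc": res.auc, "se": res.se,
                             "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "n_pos": curve.n_pos, "n_neg": curve.n_neg})
            m = optimal_threshold(scores, y, direction)
            thr_rows.append({"predictor": predictor, "cutoff": m.cutoff,
                             "sensitivity": m.sensitivity,
                             "specificity": m.specificity,
                             "ppv": m.ppv, "npv": m.npv,
                             "youden_j": m.youden_j,
                             "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn})
        rpath = os.path.join(out, "roc_results.csv")
        pd.DataFrame(roc_rows).to_csv(rpath, index=False, float_format="%.12g")
        tpath = os.path.join(out, "thresholds.csv")
        pd.DataFrame(thr_rows).to_csv(tpath, index=False, float_format="%.12g")
        artifacts["roc_results"] = rpath
        artifacts["thresholds"] = tpath
        log.info("roc: %d predictors", len(roc_rows))

    run_stage("roc", roc_stage)

    def metadata_stage():
        meta = {
            "version": __version__,
            "nca_method": config.nca_method,
            "quantile_convention": "linear interpolation between order statistics",
            "multiplicity_adjustment": "none (univariate screen)",
            "alpha": config.alpha,
            "predictors": config.predictors,
            "input_dir": config.input_dir,
            "sim": dataclasses.asdict(config.sim) if config.sim else None,
            "n_enrolled": len(cohort.patients),
            "n_analyzed": len(analyzed),
        }
        path = os.path.join(out, "run_metadata.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts["run_metadata"] = path

    run_stage("run_metadata", metadata_stage)
    return artifacts
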
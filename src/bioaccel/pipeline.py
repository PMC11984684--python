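"""End-to-end pipeline: cohort -> clocks -> acceleration -> scores -> models -> report.

Stages run in a fixed order with stage-labeled diagnostics and exclusion
bookkeeping; the machine-readable summary is serialized deterministically
(sorted keys, no timestamps) so identical config + seed gives byte-identical
output.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acceleration import build_accel_table, quantile_categories
from .behavior import ScoringRules, behavior_score_table
from .grs import GRSWeights, weighted_grs, grs_tertiles
from .hazard import (fit_ph, joint_grid, multiplicative_interaction,
                     quantile_hr_table, rcs_curve, reri_ap)
from .kdm import KDMBioAge
from .mediation import mediation_effects
from .phenoage import PhenoAgeClock, UnitSpec, PHENOAGE_BIOMARKERS
from .synth import SynthConfig, generate_cohort, generate_reference, write_cohort

logger = logging.getLogger(__name__)

REPORT_SCHEMA = {
    "required": [
        "seed", "counts", "table2", "joint_grid", "interaction", "mediation",
        "rcs", "config_echo",
    ],
    "counts_required": ["input", "after_outlier_rule", "excluded_outliers", "events"],
}


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of synth block or input paths."""

    seed: int = 0
    synth: dict | None = None          # SynthConfig fields
    cohort_path: str | None = None
    reference_path: str | None = None
    weights_path: str | None = None
    scoring_rules_path: str | None = None
    adjustments: tuple = ("model1", "model2")
    quartiles: int = 4
    bootstrap_B: int = 1000
    landmark_years: float = 0.0        # drop events in the first k follow-up years
    median_impute: bool = False
    output_dir: str = "bioaccel_out"

    def __post_init__(self):
        synth_mode = self.synth is not None
        path_mode = self.cohort_path is not None
        if synth_mode == path_mode:
            raise ValueError("exactly one of a synth block or input paths is required")
        if not synth_mode and self.reference_path is None:
            raise ValueError("input-path mode needs a reference sample for KDM training")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def sensitivity_median_impute(cohort: pd.DataFrame, panels: dict[str, list[str]]) -> tuple[pd.DataFrame, dict]:
    """Median-impute subjects with exactly one missing biomarker per panel.

    Returns the imputed table plus, per panel, the boolean mask of subjects
    eligible for that panel's biological age (at most one biomarker missing,
    which is filled with the analysis-set median; two or more leave the
    subject excluded from that panel only).
    """
    out = cohort.copy()
    masks = {}
    for panel_name, cols in panels.items():
        n_missing = out[cols].isna().sum(axis=1)
        masks[panel_name] = (n_missing <= 1).to_numpy()
        fixable = n_missing == 1
        for col in cols:
            med = out[col].median()
            fill = fixable & out[col].isna()
            out.loc[fill, col] = med
    return out, masks


def _stage(name):
    logger.info("stage: %s", name)
    return _time.perf_counter()


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def validate_report(summary: dict) -> None:
    missing = [k for k in REPORT_SCHEMA["required"] if k not in summary]
    if missing:
        raise ValueError(f"report missing sections: {missing}")
    cmissing = [k for k in REPORT_SCHEMA["counts_required"] if k not in summary["counts"]]
    if cmissing:
        raise ValueError(f"report counts missing: {cmissing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes tables + JSON summary, returns the summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts = {}

    t0 = _stage("load")
    if config.synth is not None:
        synth_cfg = SynthConfig(**{**config.synth, "seed": config.seed})
        reference = generate_reference(synth_cfg, rng)
        kdm_est = KDMBioAge().fit(reference)
        cohort = generate_cohort(synth_cfg, kdm_est.params_, rng=rng)
    else:
        reference = pd.read_csv(config.reference_path, sep="\t")
        cohort = pd.read_csv(config.cohort_path, sep="\t")
        kdm_est = KDMBioAge().fit(reference)
        rules = (ScoringRules.default() if config.scoring_rules_path is None
                 else ScoringRules(**yaml.safe_load(Path(config.scoring_rules_path).read_text())))
        if "behavior_score" not in cohort.columns:
            cohort = pd.concat([cohort, behavior_score_table(cohort, rules)], axis=1)
        if "grs" not in cohort.columns:
            weights = (GRSWeights.synthetic_default() if config.weights_path is None
                       else GRSWeights.from_file(config.weights_path))
            dosage_cols = [c for c in cohort.columns if c.startswith("snp_")]
            cohort["grs"] = weighted_grs(cohort[dosage_cols].to_numpy(float), weights)
    counts["input"] = len(cohort)
    logger.info("load done in %.2fs", _time.perf_counter() - t0)

    if config.median_impute:
        t0 = _stage("median_impute")
        panels = {"bioage": KDMBioAge.DEFAULT_PANEL, "phenoage": PHENOAGE_BIOMARKERS}
        n_miss_before = int(cohort[KDMBioAge.DEFAULT_PANEL].isna().any(axis=1).sum())
        cohort, masks = sensitivity_median_impute(cohort, panels)
        keep = masks["bioage"] & masks["phenoage"]
        counts["excluded_missing"] = int((~keep).sum())
        cohort = cohort.loc[keep].reset_index(drop=True)
        logger.info("imputed (%d rows had missing biomarkers)", n_miss_before)
    else:
        complete = cohort[KDMBioAge.DEFAULT_PANEL + PHENOAGE_BIOMARKERS].notna().all(axis=1)
        counts["excluded_missing"] = int((~complete).sum())
        cohort = cohort.loc[complete].reset_index(drop=True)

    t0 = _stage("clocks")
    cohort["bioage"] = kdm_est.predict(cohort)
    cohort["phenoage"] = PhenoAgeClock(units=UnitSpec.identity()).fit().predict(cohort)

    t0 = _stage("acceleration")
    acc = build_accel_table(cohort, ba_cols=("bioage", "phenoage"))
    table = acc.table.reset_index(drop=True)
    counts["excluded_outliers"] = acc.n_excluded
    counts["after_outlier_rule"] = len(table)

    if config.landmark_years > 0:
        t0 = _stage("landmark")
        early = (table["event"] == 1) & (table["time"] <= config.landmark_years)
        counts["excluded_landmark"] = int(early.sum())
        table = table.loc[~early].reset_index(drop=True)
    counts["events"] = int(table["event"].sum())

    t0 = _stage("scores")
    table["grs_tertile"] = grs_tertiles(table["grs"].to_numpy())
    table["behavior_tertile"] = quantile_categories(
        table["behavior_score"].to_numpy(), 3,
        labels=["unfavorable", "intermediate", "favorable"])

    t0 = _stage("hazard_models")
    table2 = {}
    rcs_block = {}
    for clock in ("bioage", "phenoage"):
        tab = quantile_hr_table(table, f"{clock}_accel_z", f"{clock}_accel_q",
                                adjustments=tuple(config.adjustments))
        table2[clock] = tab.to_dict(orient="records")
        tab.to_csv(outdir / f"table2_{clock}.tsv", sep="\t", index=False)
        curve = rcs_curve(table, f"{clock}_accel_z", adjustment=config.adjustments[-1])
        rcs_block[clock] = {"p_overall": curve.p_overall, "p_nonlinear": curve.p_nonlinear,
                            "knots": curve.knots.tolist()}
    logger.info("hazard models done in %.2fs", _time.perf_counter() - t0)

    t0 = _stage("joint_grid")
    joint_block = {}
    interaction_block = {}
    adjustment_genetic = "genetic" if all(c in table.columns for c in ("pc1", "batch")) else config.adjustments[-1]
    for clock in ("bioage", "phenoage"):
        grid = joint_grid(table, "grs_tertile", f"{clock}_accel_q", adjustment=adjustment_genetic)
        grid.to_frame().to_csv(outdir / f"joint_grid_{clock}.tsv", sep="\t", index=False)
        joint_block[clock] = grid.to_frame().to_dict(orient="records")
        hr11, hr10, hr01, sub = grid.corner_stats()
        stats_add = reri_ap(hr11, hr10, hr01, sub)
        table[f"{clock}_q4"] = (table[f"{clock}_accel_q"] == "Q4").astype(int)
        table["grs_high"] = (table["grs_tertile"] == "high").astype(int)
        p_mult, _ = multiplicative_interaction(table, "grs_high", f"{clock}_q4",
                                              adjustment=adjustment_genetic)
        interaction_block[clock] = {
            "reri": stats_add.reri, "reri_ci": list(stats_add.reri_ci),
            "ap": stats_add.ap, "ap_ci": list(stats_add.ap_ci),
            "p_multiplicative": p_mult,
        }

    t0 = _stage("mediation")
    mediation_block = {}
    table["behavior_per10"] = table["behavior_score"] / 10.0
    for clock in ("bioage", "phenoage"):
        med = mediation_effects(table, "behavior_per10", f"{clock}_accel_z",
                                B=config.bootstrap_B, seed=config.seed + 1)
        mediation_block[clock] = {
            "a": med.a, "b": med.b, "c": med.c, "c_prime": med.c_prime,
            "indirect": med.indirect, "direct": med.direct,
            "proportion": med.proportion, "proportion_alt": med.proportion_alt,
            "proportion_ci": list(med.proportion_ci) if med.proportion_ci else None,
            "B": med.B,
        }
    logger.info("mediation done in %.2fs", _time.perf_counter() - t0)

    t0 = _stage("report")
    table.to_csv(outdir / "cohort_augmented.tsv", sep="\t", index=False)
    summary = {
        "seed": config.seed,
        "counts": counts,
        "table2": table2,
        "rcs": rcs_block,
        "joint_grid": joint_block,
        "interaction": interaction_block,
        "mediation": mediation_block,
        # output_dir is environment, not analysis configuration; echoing it
        # would break byte-identity across runs into different directories
        "config_echo": _round_floats({k: v for k, v in dataclasses.asdict(config).items()
                                      if k != "output_dir"}),
    }
    summary = _round_floats(summary)
    validate_report(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
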
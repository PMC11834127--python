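"""End-to-end driver: preprocess -> features -> exclusion -> curve fits ->
statistics, with a report bundle on disk.

Every output table carries the configuration hash, so two runs with
different thresholds never share a hash, and the run log records the
exclusion bookkeeping (input = retained + excluded, per reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, config_hash
from .inference import (extreme_quintile_contrast, correlate,
                        fit_lme_candidates, paired_t_cohens_d,
                        participant_effects)
from .kinematics import build_feature_table
from .psychometrics import condition_contrast, fit_participant_curves
from .types import CohortData, GroundTruth

logger = logging.getLogger(__name__)


def _exclusion_counts(features: pd.DataFrame) -> dict:
    counts = {}
    excluded = features.loc[~features["retained"], "exclusion_reasons"]
    for reasons in excluded:
        for reason in str(reasons).split(";"):
            if reason:
                counts[reason] = counts.get(reason, 0) + 1
    return counts


def analyze_features(features: pd.DataFrame, config: AnalysisConfig = None) -> dict:
    """Statistics layer on a computed feature table.

    Returns a JSON-serializable report: retention bookkeeping, per-condition
    summaries, the Eq-curve condition contrasts, the three-model LME
    comparison, per-participant regressions with their correlations, and the
    extreme-stratum control contrast.
    """
    cfg = config or AnalysisConfig()
    n_total = len(features)
    retained = features[features["retained"]].copy()
    n_retained = len(retained)
    report = {
        "n_trials": n_total,
        "n_retained": n_retained,
        "retention_rate": n_retained / n_total if n_total else math.nan,
        "exclusion_counts": _exclusion_counts(features),
    }
    if n_retained == 0:
        report["status"] = "no trials retained; statistics skipped"
        return report
    report["status"] = "ok"

    by_cond = retained.groupby("condition")
    report["asem_velocity_signed_mean"] = {
        cond: float(v) for cond, v in
        by_cond["asem_velocity_signed"].mean().items()}
    report["latency_mean_ms"] = {
        cond: float(v * 1000.0) for cond, v in by_cond["latency"].mean().items()}

    fits = fit_participant_curves(retained)
    report["fits"] = fits.to_dict(orient="records")
    report["r2_asem_mean"] = {
        cond: float(v) for cond, v in
        fits.groupby("condition")["r2_asem"].mean().items()}
    report["r2_latency_mean"] = {
        cond: float(v) for cond, v in
        fits.groupby("condition")["r2_latency"].mean().items()}

    try:
        ctrl_a, gap_a, _ = condition_contrast(fits, "a")
        height = paired_t_cohens_d(ctrl_a, gap_a)
        report["sigmoid_height_contrast"] = dataclasses.asdict(height)
        ctrl_d, gap_d, _ = condition_contrast(fits, "d")
        offset = paired_t_cohens_d(ctrl_d, gap_d)
        report["latency_offset_contrast"] = dataclasses.asdict(offset)
    except ValueError as exc:
        report["condition_contrast_error"] = str(exc)

    usable = retained.dropna(subset=["asem_velocity_signed", "latency"])
    try:
        comparison = fit_lme_candidates(usable, min_trials=cfg.lme_min_trials)
        report["lme"] = {
            "selected": comparison.selected,
            "bic": {k: f.bic for k, f in comparison.fits.items()},
            "fixed_slope": comparison.selected_fit.fixed_slope,
            "fixed_slope_se": comparison.selected_fit.fixed_slope_se,
            "slope_t": comparison.selected_fit.slope_t,
            "slope_df": comparison.selected_fit.slope_df,
            "slope_p": comparison.selected_fit.slope_p,
            "r2_marginal": comparison.selected_fit.r2_marginal,
            "r2_conditional": comparison.selected_fit.r2_conditional,
            "singular": comparison.selected_fit.singular,
        }
    except ValueError as exc:
        report["lme_error"] = str(exc)

    regressions = participant_effects(usable, min_trials=cfg.lme_min_trials)
    report["participant_effects"] = [dataclasses.asdict(r) for r in regressions]
    if len(regressions) >= 3:
        slopes = [r.slope for r in regressions]
        r2s = [r.r_squared for r in regressions]
        lat = [r.mean_latency for r in regressions]
        r_slope, p_slope = correlate(slopes, lat)
        r_r2, p_r2 = correlate(r2s, lat)
        report["slope_vs_latency"] = {"r": r_slope, "p": p_slope}
        report["r2_vs_latency"] = {"r": r_r2, "p": p_r2}

    try:
        contrast, skipped = extreme_quintile_contrast(
            retained, fraction=cfg.extreme_fraction,
            min_cell_trials=cfg.min_cell_trials)
        report["extreme_stratum_contrast"] = dataclasses.asdict(contrast)
        report["extreme_stratum_skipped_cells"] = skipped
    except ValueError as exc:
        report["extreme_stratum_error"] = str(exc)
    return report


def _render_text_report(report: dict) -> str:
    lines = ["asemlab analysis report",
             "=======================",
             f"config hash: {report.get('config_hash', 'n/a')}",
             f"trials: {report['n_trials']}  retained: {report['n_retained']} "
             f"({report['retention_rate'] * 100:.1f}%)"]
    for reason, count in sorted(report.get("exclusion_counts", {}).items()):
        lines.append(f"  excluded ({reason}): {count}")
    if report.get("status") != "ok":
        lines.append(report.get("status", "incomplete"))
        return "\n".join(lines) + "\n"
    for cond, value in report["asem_velocity_signed_mean"].items():
        lines.append(f"ASEM velocity ({cond}): {value:.3f} deg/s")
    for cond, value in report["latency_mean_ms"].items():
        lines.append(f"interception latency ({cond}): {value:.1f} ms")
    if "sigmoid_height_contrast" in report:
        h = report["sigmoid_height_contrast"]
        lines.append(f"sigmoid height control vs gap: t({h['df']}) = {h['t']:.2f}, "
                     f"p = {h['p']:.2e}, d_z = {h['cohens_d']:.2f}")
    if "latency_offset_contrast" in report:
        h = report["latency_offset_contrast"]
        lines.append(f"latency offset control vs gap: t({h['df']}) = {h['t']:.2f}, "
                     f"p = {h['p']:.2e}, d_z = {h['cohens_d']:.2f}")
    if "lme" in report:
        lme = report["lme"]
        lines.append(f"LME selected: {lme['selected']} "
                     f"(BICs: " + ", ".join(f"{k}={v:.1f}" for k, v in lme["bic"].items()) + ")")
        lines.append(f"  fixed slope {lme['fixed_slope']:.4f} s/(deg/s) "
                     f"+- {lme['fixed_slope_se']:.4f}, "
                     f"t({lme['slope_df']}) = {lme['slope_t']:.2f}, "
                     f"p = {lme['slope_p']:.2e}")
    if "slope_vs_latency" in report:
        s = report["slope_vs_latency"]
        lines.append(f"slope vs mean latency: r = {s['r']:.2f}, p = {s['p']:.3f}")
    if "r2_vs_latency" in report:
        s = report["r2_vs_latency"]
        lines.append(f"r^2 vs mean latency: r = {s['r']:.2f}, p = {s['p']:.3f}")
    if "extreme_stratum_contrast" in report:
        e = report["extreme_stratum_contrast"]
        lines.append(f"upper vs lower ASEM stratum latency: t({e['df']}) = "
                     f"{e['t']:.2f}, p = {e['p']:.3f}, "
                     f"mean diff = {e['mean_diff'] * 1000:.1f} ms")
    return "\n".join(lines) + "\n"


def run_pipeline(cohort: CohortData, out_path,
                 config: AnalysisConfig = None,
                 ground_truth: Optional[GroundTruth] = None) -> dict:
    """Run the full analysis on a cohort and write the report bundle.

    Writes ``features.csv``, ``fits.csv`` (when computable), ``report.json``
    and ``report.txt`` under ``out_path``. Deterministic: identical inputs
    and configuration give identical numeric outputs.
    """
    cfg = config or AnalysisConfig()
    cfg.validate()
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)

    features = build_feature_table(cohort, cfg, ground_truth=ground_truth)
    features["config_hash"] = chash
    features.to_csv(out / "features.csv", index=False)

    report = analyze_features(features, cfg)
    report["config_hash"] = chash
    report["provenance"] = cohort.provenance
    if report.get("status") == "ok":
        pd.DataFrame(report["fits"]).assign(config_hash=chash).to_csv(
            out / "fits.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(out / "report.txt", "w") as fh:
        fh.write(_render_text_report(report))
    logger.info("pipeline complete: %d/%d trials retained",
                report["n_retained"], report["n_trials"])
    return report
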
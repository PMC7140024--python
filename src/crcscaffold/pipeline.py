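"""End-to-end orchestration: every analysis stage on one set of inputs.

``run_full_analysis`` takes a validated :class:`~crcscaffold.io.RunConfig`
plus whichever input tables exist (traces, plate, counts, embryos), runs
each corresponding stage, writes one CSV per stage plus a JSON roll-up
summary and a run manifest (input hashes, config, seed), and returns the
summary dict. Deterministic given config and inputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import doseresponse, permeability, quantify, stats
from .errors import CrcScaffoldError
from .io import RunConfig, file_sha256

logger = logging.getLogger("crcscaffold")
if not logger.handlers:
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_handler)
    logger.setLevel(logging.INFO)


def _stage(name):
    """Decorator: wrap stage errors with the stage name and input provenance."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CrcScaffoldError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return inner
    return wrap


@_stage("permeability")
def _permeability_stage(traces, config: RunConfig, out_dir: Path) -> dict:
    estimates = [
        permeability.fit_permeability(tr, config.geometry, config.fluid) for tr in traces
    ]
    frame = permeability.estimates_to_frame(estimates)
    frame.to_csv(out_dir / "k_estimates.csv", index=False)
    per_sample = frame.groupby(["group", "sample_id"])["k_mm4_per_Ns"].mean()
    medians = per_sample.groupby("group").median().to_dict()
    block = {"k_median_by_group_mm4_per_Ns": medians, "n_traces": len(estimates)}
    group_sizes = per_sample.groupby("group").size()
    if len(group_sizes) >= 2 and (group_sizes >= stats.MIN_GROUP_N).all():
        comparisons = permeability.compare_permeability_groups(
            estimates, parametric=config.parametric_permeability
        )
        comparisons.to_csv(out_dir / "k_group_comparisons.csv", index=False)
        block["comparisons"] = comparisons.to_dict(orient="records")
    return block


@_stage("chemosensitivity")
def _chemosensitivity_stage(plate, config: RunConfig, out_dir: Path) -> dict:
    normalized = doseresponse.normalize_viability(plate)
    table = doseresponse.viability_fold_change_table(
        normalized, parametric=config.parametric_viability
    )
    table.to_csv(out_dir / "viability_table.csv", index=False)
    at_tp = normalized[normalized["timepoint_h"] == config.timepoint_h]
    fits, fit_rows = {}, []
    for (cell, setting, drug), sub in at_tp.groupby(["cell_line", "setting", "drug"]):
        fit = doseresponse.fit_dose_response(sub)
        fits[(cell, setting, drug)] = fit
        fit_rows.append(
            {"cell_line": cell, "setting": setting, "drug": drug,
             "timepoint_h": config.timepoint_h, "ic50_uM": fit.ic50_uM,
             "hill_slope": fit.hill_slope, "top": fit.top, "bottom": fit.bottom,
             "rss": fit.rss, "n_points": fit.n_points, "converged": fit.converged}
        )
    pd.DataFrame(fit_rows).to_csv(out_dir / "ic50.csv", index=False)
    fold_changes = []
    for (cell, setting, drug), fit in fits.items():
        ref = fits.get((cell, "2D", drug))
        if setting != "2D" and ref is not None and fit.converged and ref.converged:
            fold_changes.append(
                doseresponse.compare_settings(fit, ref, labels=(setting, "2D"))
                | {"cell_line": cell, "drug": drug}
            )
    return {
        "ic50_by_condition_uM": {
            f"{c}/{s}/{d}": fits[(c, s, d)].ic50_uM for (c, s, d) in fits
        },
        "fold_changes_vs_2D": fold_changes,
        "timepoint_h": config.timepoint_h,
    }


@_stage("quantification")
def _quantification_stage(counts, out_dir: Path) -> dict:
    table = quantify.percent_positive(counts)
    table.to_csv(out_dir / "marker_percentages.csv", index=False)
    return {"marker_percentages": table.to_dict(orient="records")}


@_stage("embryo_cohort")
def _embryo_stage(embryos, config: RunConfig, out_dir: Path) -> dict:
    filtered = quantify.filter_embryo_cohort(embryos)
    filtered.retained.to_csv(out_dir / "embryos_retained.csv", index=False)
    filtered.exclusion_log.to_csv(out_dir / "embryo_exclusions.csv", index=False)
    block = {
        "n_input": int(len(embryos)),
        "n_retained": int(len(filtered.retained)),
        "n_excluded": int(len(filtered.exclusion_log)),
        "timepoints_kept_h": list(filtered.timepoints_kept_h),
        "untreated_retention_72h": filtered.untreated_retention_72h,
        "fold_change_tests": [],
    }
    analysis_tps = [tp for tp in (24, 48, 72) if tp in filtered.timepoints_kept_h]
    for tp in analysis_tps:
        fc = quantify.cohort_fold_changes(filtered, tp)
        fc.to_csv(out_dir / f"fold_change_{tp}h.csv", index=False)
        control = fc.loc[fc["arm"] == quantify.CONTROL_ARM, "fold_change"].to_numpy()
        for arm in fc["arm"].unique():
            if arm == quantify.CONTROL_ARM:
                continue
            treated = fc.loc[fc["arm"] == arm, "fold_change"].to_numpy()
            if len(control) < stats.MIN_GROUP_N or len(treated) < stats.MIN_GROUP_N:
                continue
            res = stats.two_group_test(
                treated, control, parametric=False, labels=(arm, quantify.CONTROL_ARM)
            )
            block["fold_change_tests"].append(
                {"timepoint_h": tp, "arm": arm,
                 "median_fold_change": float(np.median(treated)),
                 "control_median_fold_change": float(np.median(control)),
                 "p_value": res.p_value, "stars": res.stars}
            )
    return block


def run_full_analysis(
    config: RunConfig,
    out_dir,
    traces=None,
    plate=None,
    counts=None,
    embryos=None,
    input_paths: dict | None = None,
) -> dict:
    """Run every stage with inputs present and write per-stage CSVs + summary JSON."""
    if all(x is None for x in (traces, plate, counts, embryos)):
        raise CrcScaffoldError("no input tables provided: nothing to analyse")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {
        "geometry": asdict(config.geometry),
        "fluid": asdict(config.fluid),
        "timepoint_h": config.timepoint_h,
        "parametric_viability": config.parametric_viability,
        "parametric_permeability": config.parametric_permeability,
        "seed": config.seed,
    }}
    if traces is not None:
        logger.info("permeability stage: %d traces", len(traces))
        summary["permeability"] = _permeability_stage(traces, config, out_dir)
    if plate is not None:
        logger.info("chemosensitivity stage: %d wells", len(plate))
        summary["chemosensitivity"] = _chemosensitivity_stage(plate, config, out_dir)
    if counts is not None:
        logger.info("quantification stage: %d images", len(counts))
        summary["quantification"] = _quantification_stage(counts, out_dir)
    if embryos is not None:
        logger.info("embryo stage: %d embryos", len(embryos))
        summary["embryo_cohort"] = _embryo_stage(embryos, config, out_dir)
    manifest = {
        "seed": config.seed,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (input_paths or {}).items()
        },
        "config": summary["config"],
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
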
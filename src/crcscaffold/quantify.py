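"""Count-based marker quantification and xenograft cohort filters.

Marker positivity (Ki67/MIB1, EdU, TUNEL, E-cadherin, vimentin) is a
per-image percentage of positive over total nuclei, summarised as group
mean ± SD across images (the dispersion is labelled SD explicitly).
Drug/cell co-localization is the analogous percentage of co-localized
events over counted cells.

The zebrafish xenograft cohort applies two inclusion rules before any
fluorescence readout:

* embryos with fewer than 100 cells 2 h post-injection are discarded
  (strictly less than: a count of exactly 100 is retained);
* the 72 h timepoint is dropped from analysis when fewer than 50 % of
  untreated (control-arm) embryos still retain cells at 72 h.

Treatment effect is read out as caudal fluorescence fold change
relative to the pre-treatment (time 0) signal of the same embryo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyImageError, MissingMeasurementError

COUNT_COLUMNS = ["marker", "condition", "image_id", "positive", "total"]
EMBRYO_COLUMNS = ["embryo_id", "arm", "cells_2h", "f0", "f24", "f48", "f72"]

CELL_COUNT_MIN = 100          # embryos below this at 2 h are excluded
RETENTION_THRESHOLD = 0.5     # untreated retention needed to keep the 72 h timepoint
CONTROL_ARM = "DMSO"
FLUOR_TIMEPOINTS_H = (0, 24, 48, 72)


def percent_positive(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD percentage of positive nuclei per (marker, condition).

    Each image contributes one percentage, 100 * positive / total;
    groups are summarised across images. SD is reported with ddof=1
    (NaN for single-image groups).
    """
    if (counts["total"] <= 0).any():
        bad = counts.loc[counts["total"] <= 0, "image_id"].tolist()
        raise EmptyImageError(f"images with zero total count: {bad}")
    if (counts["positive"] > counts["total"]).any():
        raise ValueError("positive count exceeds total count")
    frame = counts.assign(pct=100.0 * counts["positive"] / counts["total"])
    out = (
        frame.groupby(["marker", "condition"])["pct"]
        .agg(mean_pct="mean", sd_pct=lambda s: s.std(ddof=1), n_images="size")
        .reset_index()
    )
    return out


def colocalization_percent(colocalized_count: int, cell_count: int) -> float:
    """Percentage of counted cells showing drug/cell co-localized events."""
    if cell_count <= 0:
        raise EmptyImageError(f"cell count must be positive, got {cell_count}")
    if colocalized_count < 0 or colocalized_count > cell_count:
        raise ValueError("colocalized count must lie in [0, cell_count]")
    return 100.0 * colocalized_count / cell_count


@dataclass(frozen=True)
class CohortFilterResult:
    """Retained embryos, the exclusion log, and the usable timepoints."""

    retained: pd.DataFrame
    exclusion_log: pd.DataFrame       # embryo_id, rule, detail
    timepoints_kept_h: tuple[int, ...]
    untreated_retention_72h: float | None


def filter_embryo_cohort(embryos: pd.DataFrame) -> CohortFilterResult:
    """Apply the cohort inclusion rules and log every removal.

    Rule 1 (per embryo): cells_2h < 100 -> excluded.
    Rule 2 (per timepoint): if the fraction of retained control-arm
    embryos flagged as retaining cells at 72 h is below 50 %, the 72 h
    timepoint is dropped for the whole analysis (no embryos are removed
    by this rule; their 72 h column is simply not analysed).

    The operation is idempotent: filtering an already-filtered cohort
    removes nothing further.
    """
    log_rows = []
    low = embryos["cells_2h"] < CELL_COUNT_MIN
    for _, row in embryos[low].iterrows():
        log_rows.append(
            {
                "embryo_id": row["embryo_id"],
                "rule": "min_cells_2h",
                "detail": f"cells_2h={row['cells_2h']} < {CELL_COUNT_MIN}",
            }
        )
    retained = embryos[~low].reset_index(drop=True)

    timepoints = list(FLUOR_TIMEPOINTS_H)
    retention = None
    control = retained[retained["arm"] == CONTROL_ARM]
    if len(control) > 0:
        if "retained_at_72h" in control.columns:
            flags = control["retained_at_72h"].astype(bool)
        else:
            # no explicit flag: an embryo retains cells at 72 h iff a
            # positive fluorescence reading exists there
            flags = control["f72"].notna() & (control["f72"] > 0)
        retention = float(flags.mean())
        if retention < RETENTION_THRESHOLD:
            timepoints.remove(72)
    log = pd.DataFrame(log_rows, columns=["embryo_id", "rule", "detail"])
    return CohortFilterResult(
        retained=retained,
        exclusion_log=log,
        timepoints_kept_h=tuple(timepoints),
        untreated_retention_72h=retention,
    )


def fluorescence_fold_change(record: pd.Series, timepoint_h: int) -> float:
    """Caudal fluorescence at a timepooint relative to the same embryo at time 0."""
    col = f"f{timepoint_h}"
    if col not in record or pd.isna(record[col]):
        raise MissingMeasurementError(
            f"embryo {record.get('embryo_id', '?')!r}: no fluorescence at {timepoint_h} h"
        )
    f0 = record["f0"]
    if pd.isna(f0) or f0 <= 0:
        raise MissingMeasurementError(
            f"embryo {record.get('embryo_id', '?')!r}: baseline fluorescence missing or <= 0"
        )
    return float(record[col] / f0)


def cohort_fold_changes(filtered: CohortFilterResult, timepoint_h: int) -> pd.DataFrame:
    """Per-embryo fold changes at one kept timepoint, tabulated by arm."""
    if timepoint_h not in filtered.timepoints_kept_h:
        raise MissingMeasurementError(
            f"timepoint {timepoint_h} h was dropped by the retention rule"
        )
    frame = filtered.retained
    return pd.DataFrame(
        {
            "embryo_id": frame["embryo_id"],
            "arm": frame["arm"],
            "fold_change": [
                fluorescence_fold_change(row, timepoint_h) for _, row in frame.iterrows()
            ],
        }
    )
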
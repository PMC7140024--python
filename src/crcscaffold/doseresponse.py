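"""Chemosensitivity analysis: viability normalisation and IC50 estimation.

Raw plate-reader signals are standardised to the mean untreated control
of the same culture setting and timepoint (so untreated = 100 %), then
dose-response curves are fitted per (cell line, setting, drug,
timepoint) with the four-parameter logistic (Hill) model on log10
concentration,

.. math:: V(c) = bottom + \\frac{top - bottom}
                 {1 + 10^{\\,slope\\,(\\log_{10} c - \\log_{10} IC_{50})}}

with slope > 0 in this inhibitory parameterisation (viability falls as
concentration rises). The 3D-vs-2D sensitivity shift is the ratio of
fitted IC50s.

Combination drugs dosed at a fixed ratio (e.g. the 5FU:leucovorin:
irinotecan 25:5:1 cocktail) are indexed by their principal-component
concentration, so their IC50s are commensurate with single-agent values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import stats
from .errors import FlatResponseError, MissingControlError

PLATE_COLUMNS = [
    "cell_line", "setting", "drug", "conc_uM", "timepoint_h",
    "replicate", "signal", "is_untreated",
]

DEFAULT_TIMEPOINT_H = 72
DEFAULT_CONC_GRID_UM = (0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class HillFit:
    """Fitted four-parameter logistic dose-response model."""

    ic50_uM: float
    hill_slope: float
    top: float
    bottom: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, conc_uM) -> np.ndarray:
        """Model viability (%) at the given concentrations (µM)."""
        c = np.asarray(conc_uM, dtype=float)
        return hill_curve(c, self.ic50_uM, self.hill_slope, self.top, self.bottom)


def hill_curve(conc_uM, ic50_uM, hill_slope, top, bottom):
    """Inhibitory 4PL evaluated at concentration(s), vectorised."""
    logc = np.log10(np.asarray(conc_uM, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill_slope * (logc - np.log10(ic50_uM))))


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Standardise signals to the untreated controls of each (setting, timepoint).

    Returns the treated records with a ``viability_pct`` column: raw
    signal divided by the mean untreated signal of the matching
    (cell_line, setting, drug, timepoint) stratum, x100. Raises
    :class:`MissingControlError` naming any stratum without controls.
    """
    strata = ["cell_line", "setting", "drug", "timepoint_h"]
    controls = plate[plate["is_untreated"].astype(bool)]
    control_mean = controls.groupby(strata)["signal"].mean().rename("control_mean")
    treated = plate[~plate["is_untreated"].astype(bool)].copy()
    merged = treated.merge(control_mean, on=strata, how="left")
    if merged["control_mean"].isna().any():
        missing = merged.loc[merged["control_mean"].isna(), strata].drop_duplicates()
        raise MissingControlError(
            "no untreated control wells for strata:\n" + missing.to_string(index=False)
        )
    merged["viability_pct"] = 100.0 * merged["signal"] / merged["control_mean"]
    return merged.drop(columns="control_mean")


def fit_dose_response(
    records: pd.DataFrame,
    conc_col: str = "conc_uM",
    value_col: str = "viability_pct",
) -> HillFit:
    """Least-squares 4PL fit on log10 concentration from well-level points.

    Wells are fitted individually (never pre-averaged) to preserve the
    replicate error structure. The top plateau is initialised — not
    fixed — at 100 % and the bottom bounded in [0, top]; the slope is
    constrained positive, so no multistart over slope sign is needed for
    inhibitors. A small multistart over the midpoint guards against the
    rare local minimum on sparse 4-point grids.
    """
    data = records[records[conc_col] > 0]
    conc = data[conc_col].to_numpy(dtype=float)
    resp = data[value_col].to_numpy(dtype=float)
    if np.unique(conc).size < 3:
        raise FlatResponseError(
            f"need >= 3 distinct positive concentrations, got {np.unique(conc).size}"
        )
    if np.ptp(resp) == 0:
        raise FlatResponseError("all responses identical: no dose-response to fit")
    logc = np.log10(conc)

    def residuals(params):
        log_ic50, slope, top, bottom = params
        return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - log_ic50))) - resp

    lo = np.array([logc.min() - 3.0, 0.05, 1.0, 0.0])
    hi = np.array([logc.max() + 3.0, 10.0, 300.0, 150.0])
    top0 = 100.0
    bottom0 = max(0.0, min(float(resp.min()), 100.0))
    best = None
    for log_ic50_0 in (float(np.median(logc)), float(logc.min()) + 0.5, float(logc.max()) - 0.5):
        x0 = np.clip([log_ic50_0, 1.0, top0, bottom0], lo, hi)
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    log_ic50, slope, top, bottom = best.x
    converged = bool(best.success) and bottom <= top
    return HillFit(
        ic50_uM=float(10.0**log_ic50),
        hill_slope=float(slope),
        top=float(top),
        bottom=float(bottom),
        rss=float(2.0 * best.cost),
        n_points=len(resp),
        converged=converged,
    )


def compare_settings(fit_a: HillFit, fit_b: HillFit, labels=("a", "b")) -> dict:
    """IC50 fold change between two fitted settings.

    A ratio > 1 means setting ``a`` is less drug-sensitive than ``b``
    (e.g. the resistance shift of 3D scaffold culture over 2D
    monolayers). Both fits must have converged.
    """
    for label, fit in zip(labels, (fit_a, fit_b)):
        if not fit.converged:
            raise FlatResponseError(f"unusable (non-converged) fit for setting {label!r}")
    return {
        "setting_a": labels[0],
        "setting_b": labels[1],
        "ic50_a_uM": fit_a.ic50_uM,
        "ic50_b_uM": fit_b.ic50_uM,
        "fold_change": fit_a.ic50_uM / fit_b.ic50_uM,
    }


def viability_fold_change_table(
    normalized: pd.DataFrame,
    reference_setting: str = "2D",
    parametric: bool = True,
) -> pd.DataFrame:
    """Mean ± SEM viability per (setting, concentration, timepoint) with tests.

    Each non-reference setting is compared against the reference at every
    (drug, concentration, timepoint) via the two-group toolkit; single
    replicate strata report SEM as NaN and no test.
    """
    keys = ["cell_line", "drug", "timepoint_h", "conc_uM", "setting"]
    grouped = normalized.groupby(keys)["viability_pct"]
    table = grouped.agg(mean_viability_pct="mean", n_wells="size").reset_index()
    table["sem_viability_pct"] = grouped.sem().to_numpy()
    table["p_vs_reference"] = np.nan
    table["stars_vs_reference"] = ""
    strat_keys = ["cell_line", "drug", "timepoint_h", "conc_uM"]
    for strat, sub in normalized.groupby(strat_keys):
        ref = sub.loc[sub["setting"] == reference_setting, "viability_pct"].to_numpy()
        for setting in sub["setting"].unique():
            if setting == reference_setting:
                continue
            other = sub.loc[sub["setting"] == setting, "viability_pct"].to_numpy()
            if len(ref) < stats.MIN_GROUP_N or len(other) < stats.MIN_GROUP_N:
                continue
            result = stats.two_group_test(
                other, ref, parametric, labels=(setting, reference_setting)
            )
            mask = np.logical_and.reduce(
                [table[k] == v for k, v in zip(strat_keys, strat)] + [table["setting"] == setting]
            )
            table.loc[mask, "p_vs_reference"] = result.p_value
            table.loc[mask, "stars_vs_reference"] = result.stars
    return table
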
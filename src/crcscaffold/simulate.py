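"""Seed-deterministic generators for every input kind the pipeline reads.

Each generator emulates the statistical structure of one bench readout:

* filtration traces — exponential column decay sampled over the
  210 -> 100 mm descent with multiplicative reading noise (a graduated
  pipette has roughly constant *relative* precision);
* grouped permeability scenarios — log-normal K per tissue group, with
  the default ordering fresh < recellularized (3DT) < decellularized;
* dose-response plates — inhibitory Hill viability plus additive noise
  on the 0.1-100 µM grid with untreated control wells;
* marker count tables — binomial positives per image;
* zebrafish xenograft cohorts — Poisson cell uptake around ~200 cells,
  per-arm retention probabilities, and log-normal multiplicative
  fluorescence decline per 24 h.

All randomness flows through one ``numpy.random.Generator`` seeded from
the caller, so identical parameters and seed are bit-reproducible.

The default K magnitudes are synthetic: chosen so a simulated descent
completes within minutes of simulated time, not transcribed from any
instrument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doseresponse import DEFAULT_CONC_GRID_UM, hill_curve
from .filtration import DeviceGeometry, FluidProperties, column_height, time_to_height
from .permeability import FiltrationTrace

#: Synthetic per-group median permeabilities, mm^4/(N s).
DEFAULT_GROUP_MEDIANS = {
    "fresh": 50.0,
    "recellularized_3DT": 500.0,
    "decellularized": 5000.0,
}
DEFAULT_LOG_SD = 0.5
DEFAULT_N_PER_GROUP = 8        # matches the reference-material protocol size
DEFAULT_TRACE_POINTS = 50
DEFAULT_HEIGHT_NOISE_REL = 0.01

DEFAULT_EMBRYOS_PER_ARM = 50   # stated minimum cohort size per group
DEFAULT_MEAN_CELLS = 200.0     # ~200 cells implanted per embryo


def gen_filtration_trace(
    k_true: float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
    n_points: int = DEFAULT_TRACE_POINTS,
    noise_sd_rel: float = DEFAULT_HEIGHT_NOISE_REL,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    group: str = "reference_material",
    repeat_index: int = 0,
) -> FiltrationTrace:
    """One falling-head trace over the analysis window with relative noise.

    Times are spaced uniformly between t0 = 0 and the time the column
    reaches the window floor (so the whole descent is observed); heights
    are the closed-form decay times (1 + eps), eps ~ N(0, noise_sd_rel).
    The first point sits exactly at H(t0) before noise.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, _ = geom.analysis_window_mm
    if k_true > 0:
        t_end = time_to_height(lo, k_true, geom, fluid, t0=0.0)
    else:
        t_end = float(n_points)  # arbitrary span: the column never moves
    times = np.linspace(0.0, t_end, n_points)
    clean = column_height(times, 0.0, k_true, geom, fluid)
    eps = rng.normal(0.0, noise_sd_rel, size=n_points) if noise_sd_rel > 0 else 0.0
    heights = np.maximum(clean * (1.0 + eps), 1e-9)
    return FiltrationTrace(sample_id, group, times, heights, repeat_index)


def gen_reliability_traces(
    k_true: float = 1000.0,
    n_samples: int = 8,
    n_repeats: int = 5,
    noise_sd_rel: float = DEFAULT_HEIGHT_NOISE_REL,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
    seed: int = 0,
) -> list[FiltrationTrace]:
    """The device-validation protocol: repeats x samples on one reference material."""
    rng = np.random.default_rng(seed)
    traces = []
    for s in range(n_samples):
        for r in range(n_repeats):
            traces.append(
                gen_filtration_trace(
                    k_true, geom, fluid, noise_sd_rel=noise_sd_rel, seed=rng,
                    sample_id=f"ref{s + 1}", group="reference_material", repeat_index=r,
                )
            )
    return traces


def gen_group_permeabilities(
    median_by_group: dict[str, float] | None = None,
    log_sd: float = DEFAULT_LOG_SD,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    noise_sd_rel: float = DEFAULT_HEIGHT_NOISE_REL,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
    seed: int = 0,
) -> tuple[list[FiltrationTrace], pd.DataFrame]:
    """Grouped tissue scenario: log-normal K per group rendered as traces.

    Returns the traces plus a truth table (sample_id, group, k_true).
    ``log_sd`` is the standard deviation of ln K within a group.
    """
    medians = dict(DEFAULT_GROUP_MEDIANS if median_by_group is None else median_by_group)
    rng = np.random.default_rng(seed)
    traces, truth = [], []
    for group, median in medians.items():
        k_draws = median * np.exp(rng.normal(0.0, log_sd, size=n_per_group))
        for i, k in enumerate(k_draws):
            sid = f"{group}_{i + 1}"
            traces.append(
                gen_filtration_trace(
                    float(k), geom, fluid, noise_sd_rel=noise_sd_rel, seed=rng,
                    sample_id=sid, group=group,
                )
            )
            truth.append({"sample_id": sid, "group": group, "k_true": float(k)})
    return traces, pd.DataFrame(truth)


def gen_dose_response(
    ic50_true_uM: float,
    hill_slope: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    conc_grid_uM: tuple = DEFAULT_CONC_GRID_UM,
    n_reps: int = 3,
    noise_sd_pp: float = 5.0,
    control_signal: float = 1.0,
    seed: int = 0,
    cell_line: str = "HT29",
    setting: str = "2D",
    drug: str = "5FU",
    timepoint_h: int = 72,
) -> pd.DataFrame:
    """Well-level plate table for one condition: Hill viability + noise.

    Raw signals are scaled so the mean untreated well sits at
    ``control_signal``; treated wells carry the Hill viability fraction
    of that level plus additive noise of ``noise_sd_pp`` percentage
    points. Returns the plate schema (is_untreated wells at conc 0).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for rep in range(n_reps):
        v_ctrl = 100.0 + (rng.normal(0.0, noise_sd_pp) if noise_sd_pp > 0 else 0.0)
        rows.append((0.0, rep, control_signal * v_ctrl / 100.0, True))
        for conc in conc_grid_uM:
            v = hill_curve(conc, ic50_true_uM, hill_slope, top, bottom)
            v = v + (rng.normal(0.0, noise_sd_pp) if noise_sd_pp > 0 else 0.0)
            rows.append((float(conc), rep, control_signal * v / 100.0, False))
    return pd.DataFrame(
        {
            "cell_line": cell_line,
            "setting": setting,
            "drug": drug,
            "conc_uM": [r[0] for r in rows],
            "timepoint_h": timepoint_h,
            "replicate": [r[1] for r in rows],
            "signal": [r[2] for r in rows],
            "is_untreated": [r[3] for r in rows],
        }
    )


def gen_ic50_shift_plate(
    ic50_2d_uM: float = 1.3,
    ic50_3d_uM: float = 11.58,
    hill_slope: float = 1.0,
    n_reps: int = 3,
    noise_sd_pp: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-setting scenario reproducing a ~9-fold 3D-over-2D IC50 shift."""
    rng = np.random.default_rng(seed)
    plates = [
        gen_dose_response(ic50_2d_uM, hill_slope, n_reps=n_reps,
                          noise_sd_pp=noise_sd_pp, seed=rng, setting="2D"),
        gen_dose_response(ic50_3d_uM, hill_slope, n_reps=n_reps,
                          noise_sd_pp=noise_sd_pp, seed=rng, setting="3DT"),
    ]
    return pd.concat(plates, ignore_index=True)


def gen_count_table(
    p_by_condition: dict[str, float],
    marker: str = "Ki67",
    n_nuclei: int = 400,
    n_images: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial marker-count table: per image, positives ~ Bin(n_nuclei, p)."""
    rng = np.random.default_rng(seed)
    rows = []
    for condition, p in p_by_condition.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {condition!r} must be in [0, 1], got {p}")
        positives = rng.binomial(n_nuclei, p, size=n_images)
        for i, pos in enumerate(positives):
            rows.append(
                {
                    "marker": marker, "condition": condition,
                    "image_id": f"{condition}_img{i + 1}",
                    "positive": int(pos), "total": n_nuclei,
                }
            )
    return pd.DataFrame(rows)


def gen_embryo_cohort(
    n_per_arm: int = DEFAULT_EMBRYOS_PER_ARM,
    mean_cells: float = DEFAULT_MEAN_CELLS,
    retention_by_arm: dict[str, float] | None = None,
    decline_by_arm: dict[str, float] | None = None,
    decline_log_sd: float = 0.15,
    f0_mean: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Zebrafish xenograft cohort with per-arm retention and decline.

    Per embryo: cells at 2 h ~ Poisson(mean_cells); baseline caudal
    fluorescence f0 proportional to the cell count; each subsequent
    24 h multiplies the signal by the arm's decline factor times
    log-normal noise. Retention at 72 h is Bernoulli per arm; embryos
    that do not retain cells read 0 fluorescence at 72 h.
    """
    retention = {"DMSO": 0.45, "IC50_2D": 0.45, "IC50_3D": 0.3} \
        if retention_by_arm is None else retention_by_arm
    # default declines emulate an active 3D-level dose and a 2D-level dose
    # too weak to act in vivo (indistinguishable from control drift)
    decline = {"DMSO": 0.95, "IC50_2D": 0.93, "IC50_3D": 0.4} \
        if decline_by_arm is None else decline_by_arm
    rng = np.random.default_rng(seed)
    rows = []
    for arm in retention:
        cells = rng.poisson(mean_cells, size=n_per_arm)
        for i in range(n_per_arm):
            f0 = f0_mean * cells[i] / mean_cells
            signal, fluor = f0, {"f0": f0}
            for tp in (24, 48, 72):
                signal = signal * decline[arm] * np.exp(rng.normal(0.0, decline_log_sd))
                fluor[f"f{tp}"] = signal
            if rng.random() >= retention[arm]:
                fluor["f72"] = 0.0
            rows.append(
                {"embryo_id": f"{arm}_e{i + 1}", "arm": arm,
                 "cells_2h": int(cells[i]), **fluor}
            )
    return pd.DataFrame(rows, columns=EMBRYO_SCHEMA)


EMBRYO_SCHEMA = ["embryo_id", "arm", "cells_2h", "f0", "f24", "f48", "f72"]
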
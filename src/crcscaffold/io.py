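"""CSV readers/writers and run configuration.

All tabular interchange is CSV with a header row, UTF-8, '.' decimal,
and unit-suffixed column names (``height_mm``, ``conc_uM``, ...) so no
artifact file carries bare-unit ambiguity. Readers validate the schema
and report malformed rows with their line numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .doseresponse import PLATE_COLUMNS
from .errors import SchemaError
from .filtration import DeviceGeometry, FluidProperties
from .permeability import FiltrationTrace
from .quantify import COUNT_COLUMNS, EMBRYO_COLUMNS

TRACE_COLUMNS = ["sample_id", "group", "repeat", "time_s", "height_mm"]


def _read_csv(path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    frame = pd.read_csv(path)
    if frame.empty:
        raise SchemaError(f"{name} file is empty: {path}")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} file {path} is missing column(s): {missing}")
    return frame


def _check_numeric(frame: pd.DataFrame, cols: list[str], name: str) -> None:
    for col in cols:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (frame.index[bad] + 2).tolist()
            raise SchemaError(f"{name}: non-numeric {col!r} at line(s) {lines}")
        frame[col] = pd.to_numeric(frame[col], errors="coerce")


def read_traces(path) -> list[FiltrationTrace]:
    """Read filtration traces (sample_id, group, repeat, time_s, height_mm)."""
    frame = _read_csv(path, TRACE_COLUMNS, "traces")
    _check_numeric(frame, ["time_s", "height_mm"], "traces")
    traces = []
    for (sid, group, rep), sub in frame.groupby(["sample_id", "group", "repeat"], sort=False):
        sub = sub.sort_values("time_s")
        traces.append(
            FiltrationTrace(str(sid), str(group), sub["time_s"].to_numpy(),
                            sub["height_mm"].to_numpy(), int(rep))
        )
    return traces


def write_traces(traces: list[FiltrationTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, h in zip(tr.times_s, tr.heights_mm):
            rows.append((tr.sample_id, tr.group, tr.repeat_index, t, h))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_plate(path) -> pd.DataFrame:
    """Read a viability plate table (well-level raw signals)."""
    frame = _read_csv(path, PLATE_COLUMNS, "plate")
    _check_numeric(frame, ["conc_uM", "timepoint_h", "signal"], "plate")
    if (frame["conc_uM"] < 0).any():
        raise SchemaError("plate: negative concentrations present")
    frame["is_untreated"] = frame["is_untreated"].astype(bool)
    return frame


def read_counts(path) -> pd.DataFrame:
    """Read a marker count table (positive/total nuclei per image)."""
    frame = _read_csv(path, COUNT_COLUMNS, "counts")
    _check_numeric(frame, ["positive", "total"], "counts")
    if (frame["positive"] < 0).any() or (frame["positive"] > frame["total"]).any():
        raise SchemaError("counts: positive must lie in [0, total]")
    return frame


def read_embryos(path) -> pd.DataFrame:
    """Read a xenograft cohort table (cells at 2 h, fluorescence time course)."""
    frame = _read_csv(path, EMBRYO_COLUMNS, "embryos")
    _check_numeric(frame, ["cells_2h", "f0", "f24", "f48", "f72"], "embryos")
    return frame


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    geometry: DeviceGeometry = DeviceGeometry()
    fluid: FluidProperties = FluidProperties()
    timepoint_h: int = 72
    parametric_viability: bool = True
    parametric_permeability: bool = False
    seed: int = 0

    _GEOM_KEYS = {
        "sample_diameter_mm", "sample_thickness_mm", "pipette_inner_diameter_mm",
        "initial_height_mm", "analysis_window_mm",
    }
    _FLUID_KEYS = {"specific_weight_N_per_mm3"}
    _TOP_KEYS = {"geometry", "fluid", "timepoint_h", "parametric_viability",
                 "parametric_permeability", "seed"}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls._TOP_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        geom_block = dict(data.get("geometry", {}))
        unknown = set(geom_block) - cls._GEOM_KEYS
        if unknown:
            raise SchemaError(f"unknown geometry key(s): {sorted(unknown)}")
        if "analysis_window_mm" in geom_block:
            geom_block["analysis_window_mm"] = tuple(geom_block["analysis_window_mm"])
        fluid_block = dict(data.get("fluid", {}))
        unknown = set(fluid_block) - cls._FLUID_KEYS
        if unknown:
            raise SchemaError(f"unknown fluid key(s): {sorted(unknown)}")
        return cls(
            geometry=DeviceGeometry(**geom_block),
            fluid=FluidProperties(**fluid_block),
            timepoint_h=int(data.get("timepoint_h", 72)),
            parametric_viability=bool(data.get("parametric_viability", True)),
            parametric_permeability=bool(data.get("parametric_permeability", False)),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def file_sha256(path) -> str:
    """Hex digest of a file, for the run manifest."""
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
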
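"""Forward model of the falling-head tissue permeameter.

A cylindrical tissue specimen (cross-section ``A_s``, thickness ``dx``)
is clamped between porous plates below a vertical pipette of
cross-section ``A_p``. The fluid column of height ``H(t)`` drives flow
through the specimen under Darcy's law,

.. math:: Q = K \\, A_s \\, \\gamma \\, H(t) / \\Delta x,

where ``K`` is the hydraulic permeability coefficient (mm^4 N^-1 s^-1)
and ``gamma`` the specific weight of the permeating fluid. Combining
Darcy's law with continuity between pipette and specimen
(``A_p dH/dt = -Q``) and integrating gives the closed-form exponential
column decay

.. math:: H(t) = H(t_0)\\, e^{-\\lambda (t - t_0)},
          \\qquad \\lambda = K \\frac{A_s}{A_p} \\frac{\\gamma}{\\Delta x}.

All lengths are millimetres, forces newtons, times seconds; ``K`` is
therefore in mm^4/(N s), the unit the device reports. Converters to SI
are provided but not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidGeometryError,
    InvalidHeightError,
    InvalidTimeOrderError,
    UnreachableHeightError,
)

#: Specific weight of water at lab temperature, N/mm^3 (= 9.81 kN/m^3).
GAMMA_WATER_N_PER_MM3 = 9.81e-6


@dataclass(frozen=True)
class DeviceGeometry:
    """Physical constants of the falling-head permeameter.

    Defaults encode the bench device: a 3 mm diameter x 2 mm thick
    specimen chamber under a 6 mm internal-diameter pipette filled to
    210 mm, with heights analysed inside the closed 210-100 mm window.
    """

    sample_diameter_mm: float = 3.0
    sample_thickness_mm: float = 2.0
    pipette_inner_diameter_mm: float = 6.0
    initial_height_mm: float = 210.0
    analysis_window_mm: tuple[float, float] = (100.0, 210.0)

    def __post_init__(self) -> None:
        for name in (
            "sample_diameter_mm",
            "sample_thickness_mm",
            "pipette_inner_diameter_mm",
            "initial_height_mm",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidGeometryError(f"{name} must be strictly positive, got {value!r}")
        lo, hi = self.analysis_window_mm
        if not (0 < lo <= hi <= self.initial_height_mm):
            raise InvalidGeometryError(
                "analysis_window_mm must satisfy 0 < low <= high <= initial_height_mm, "
                f"got {self.analysis_window_mm!r} with initial height {self.initial_height_mm}"
            )

    @property
    def sample_area_mm2(self) -> float:
        """Transversal section of the specimen, A_s."""
        return math.pi * (self.sample_diameter_mm / 2.0) ** 2

    @property
    def pipette_area_mm2(self) -> float:
        """Transversal section of the pipette, A_p."""
        return math.pi * (self.pipette_inner_diameter_mm / 2.0) ** 2

    @property
    def area_ratio(self) -> float:
        """A_s / A_p — the geometric factor scaling column descent speed."""
        return self.sample_area_mm2 / self.pipette_area_mm2


@dataclass(frozen=True)
class FluidProperties:
    """Specific weight gamma of the permeating fluid, N/mm^3."""

    specific_weight_N_per_mm3: float = GAMMA_WATER_N_PER_MM3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.specific_weight_N_per_mm3) and self.specific_weight_N_per_mm3 > 0):
            raise InvalidGeometryError(
                f"specific weight must be strictly positive, got {self.specific_weight_N_per_mm3!r}"
            )


@dataclass(frozen=True)
class Permeability:
    """Hydraulic permeability coefficient K, mm^4/(N s)."""

    k_mm4_per_Ns: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_mm4_per_Ns) and self.k_mm4_per_Ns >= 0):
            raise InvalidGeometryError(f"permeability must be >= 0, got {self.k_mm4_per_Ns!r}")


def _as_k(k: "Permeability | float") -> float:
    value = k.k_mm4_per_Ns if isinstance(k, Permeability) else float(k)
    if not (math.isfinite(value) and value >= 0):
        raise InvalidGeometryError(f"permeability must be >= 0, got {k!r}")
    return value


def decay_rate(
    k: Permeability | float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Exponential decay rate lambda = K * (A_s/A_p) * gamma / dx, in 1/s.

    Zero exactly when the specimen is impermeable (K = 0).
    """
    kv = _as_k(k)
    return kv * geom.area_ratio * fluid.specific_weight_N_per_mm3 / geom.sample_thickness_mm


def column_height(
    t: float | np.ndarray,
    t0: float,
    k: Permeability | float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> float | np.ndarray:
    """Closed-form fluid-column height H(t) = H(t0) exp(-lambda (t - t0)), mm.

    Vectorised over ``t``; raises for any observation before ``t0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0):
        raise InvalidTimeOrderError(f"all times must be >= t0 = {t0}")
    rate = decay_rate(k, geom, fluid)
    out = geom.initial_height_mm * np.exp(-rate * (t_arr - t0))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def darcy_flux(
    k: Permeability | float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
    h_mm: float = None,
) -> float:
    """Darcy volumetric flux Q = K * A_s * gamma * H / dx through the specimen, mm^3/s."""
    if h_mm is None or h_mm < 0:
        raise InvalidHeightError(f"height must be a non-negative number, got {h_mm!r}")
    kv = _as_k(k)
    return kv * geom.sample_area_mm2 * fluid.specific_weight_N_per_mm3 * h_mm / geom.sample_thickness_mm


def pressure_gradient(
    h_mm: float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> float:
    """Pressure gradient across the specimen at column height h, in kPa/mm.

    gamma * h is the driving pressure (N/mm^2 = MPa); dividing by the
    specimen thickness and converting MPa -> kPa gives kPa/mm. At the
    default geometry the 210-100 mm analysis window corresponds to
    1.03-0.49 kPa/mm.
    """
    if h_mm < 0:
        raise InvalidHeightError(f"height must be >= 0, got {h_mm!r}")
    mpa_per_mm = fluid.specific_weight_N_per_mm3 * h_mm / geom.sample_thickness_mm
    return mpa_per_mm * 1000.0


def time_to_height(
    h_target_mm: float,
    k: Permeability | float,
    geom: DeviceGeometry = DeviceGeometry(),
    fluid: FluidProperties = FluidProperties(),
    t0: float = 0.0,
) -> float:
    """Analytic inverse of the column decay: time at which H(t) = h_target.

    Requires 0 < h_target <= H(t0); an impermeable specimen never
    reaches any height below the start.
    """
    h0 = geom.initial_height_mm
    if not (0 < h_target_mm <= h0):
        raise InvalidHeightError(f"target height must lie in (0, {h0}], got {h_target_mm!r}")
    if h_target_mm == h0:
        return t0
    rate = decay_rate(k, geom, fluid)
    if rate == 0.0:
        raise UnreachableHeightError(
            f"K = 0: column never descends from {h0} mm to {h_target_mm} mm"
        )
    return t0 + math.log(h0 / h_target_mm) / rate


def k_to_si(k_mm4_per_Ns: float) -> float:
    """Convert K from mm^4/(N s) to m^4/(N s)."""
    return k_mm4_per_Ns * 1e-12


def k_from_si(k_m4_per_Ns: float) -> float:
    """Convert K from m^4/(N s) to mm^4/(N s)."""
    return k_m4_per_Ns * 1e12
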
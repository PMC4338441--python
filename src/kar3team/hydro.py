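"""Native molecular weight from hydrodynamic measurements.

Combines a Stokes radius (size-exclusion chromatography) with a
sedimentation coefficient (sucrose gradient) via the Siegel-Monty relation

    M = 6 * pi * eta * N_A * Rs * s / (1 - vbar * rho)

plus linear interpolation against calibration standards for both axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

__all__ = ["HydroInput", "native_mw", "interpolate_standard"]

#: water at 20 C
ETA_WATER_20C = 1.002e-3   # Pa s
RHO_WATER_20C = 0.9982     # g/cm^3
VBAR_PROTEIN = 0.73        # cm^3/g, typical protein


@dataclass(frozen=True)
class HydroInput:
    rs_nm: float                      # Stokes radius
    s_svedberg: float                 # sedimentation coefficient (1 S = 1e-13 s)
    vbar_cm3_g: float = VBAR_PROTEIN  # partial specific volume
    eta_pa_s: float = ETA_WATER_20C   # solvent viscosity
    rho_g_cm3: float = RHO_WATER_20C  # solvent density

    def __post_init__(self) -> None:
        if self.rs_nm <= 0 or self.s_svedberg < 0:
            raise ValueError("Rs must be > 0 and s must be >= 0")
        if self.vbar_cm3_g <= 0 or self.eta_pa_s <= 0 or self.rho_g_cm3 <= 0:
            raise ValueError("vbar, eta and rho must be > 0")
        if self.vbar_cm3_g * self.rho_g_cm3 >= 1:
            raise ValueError("vbar * rho >= 1: buoyancy term undefined")


def native_mw(h: HydroInput) -> float:
    """Native molecular weight in kDa.

    All quantities are converted to SI; the result in kg/mol is numerically
    the mass in kDa (1 kg/mol = 1 kDa).
    """
    rs_m = h.rs_nm * 1e-9
    s_si = h.s_svedberg * 1e-13
    m_kg_mol = (
        6.0 * np.pi * h.eta_pa_s * Avogadro * rs_m * s_si
        / (1.0 - h.vbar_cm3_g * h.rho_g_cm3)
    )
    return float(m_kg_mol)


def interpolate_standard(
    calibration: pd.DataFrame,
    observed: float,
    coord_col: str = "observed",
    value_col: str = "value",
) -> float:
    """Evaluate the least-squares calibration line at ``observed``.

    ``calibration`` needs >= 2 standards with columns ``coord_col`` (elution
    volume / fraction index) and ``value_col`` (known Rs or s).  Queries
    beyond 10% outside the calibrated span raise an extrapolation warning.
    """
    if len(calibration) < 2:
        raise ValueError("need at least 2 calibration standards")
    xs = calibration[coord_col].to_numpy(float)
    ys = calibration[value_col].to_numpy(float)
    span = xs.max() - xs.min()
    if observed < xs.min() - 0.1 * span or observed > xs.max() + 0.1 * span:
        warnings.warn(
            f"query {observed} extrapolates beyond 10% of the calibrated span",
            stacklevel=2,
        )
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope * observed + intercept)
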
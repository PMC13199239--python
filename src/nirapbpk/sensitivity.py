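"""Local sensitivity of steady-state tissue exposure to drug parameters.

Each of the five calibrated parameters is varied independently from 85%
to 115% of its final value in 1% steps (31 grid points).  Every point is
a full re-simulation: perturbations of logP and pKa propagate through
the partition, binding and permeability coefficients, not just through
ODE rate constants — the pH ion-trap makes the pKa response of
intracellular unbound AUC_ss genuinely non-linear, with an interior
maximum in acid-inside tissues, while the clearance and permeability
parameters act near-linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    DoseRegimen,
    DrugParameters,
    FormulationParameters,
    PBPKModel,
    SolverSettings,
)
from .physiology import ReferenceIndividual

__all__ = [
    "SCANNED_PARAMETERS",
    "SensitivityScan",
    "ShapeClassification",
    "scan_parameter",
    "classify_response",
    "default_multipliers",
]

SCANNED_PARAMETERS = ("logP", "pKa", "p_int", "cl_ren", "cl_spec")
DEFAULT_ORGANS = ("bone", "gonads", "muscle", "heart", "kidney", "lung",
                  "liver", "brain", "small_intestine")
STEADY_STATE_WINDOW_H = (648.0, 672.0)


def default_multipliers() -> np.ndarray:
    """The 85%–115% grid in 1% steps (31 points, includes 1.00)."""
    return np.round(np.arange(0.85, 1.15 + 1e-9, 0.01), 10)


@dataclass
class SensitivityScan:
    """AUC_ss response of every organ along one parameter's grid."""

    parameter: str
    multipliers: np.ndarray
    auc: pd.DataFrame                 # index: organ, columns: multiplier
    plasma_auc: pd.Series             # per multiplier
    reference_index: int

    @property
    def reference(self) -> pd.Series:
        return self.auc.iloc[:, self.reference_index]


@dataclass(frozen=True)
class ShapeClassification:
    """Shape of one organ's response over the grid."""

    shape: str                        # near-linear | interior-maximum | interior-minimum
    location: float | None            # grid multiplier of the extremum
    r_squared: float


def scan_parameter(name: str,
                   drug: DrugParameters,
                   individual: ReferenceIndividual,
                   formulation: FormulationParameters | None = None,
                   settings: SolverSettings | None = None,
                   regimen: DoseRegimen | None = None,
                   organs: Sequence[str] = DEFAULT_ORGANS,
                   multipliers: np.ndarray | None = None) -> SensitivityScan:
    """Simulate the 31-point local scan for one parameter.

    Failed grid points are recorded as missing (with a warning) rather
    than aborting the scan.  Deterministic: repeated scans are identical.
    """
    if name not in SCANNED_PARAMETERS:
        raise ValueError(f"unknown parameter {name!r}")
    regimen = regimen or DoseRegimen.qd(300.0, 28)
    mults = default_multipliers() if multipliers is None else np.asarray(multipliers)
    ref_idx = int(np.argmin(np.abs(mults - 1.0)))

    records = {o: [] for o in organs}
    plasma = []
    base_value = getattr(drug, name)
    for m in mults:
        d = drug.replace(**{name: base_value * float(m)})
        try:
            model = PBPKModel(d, individual, formulation, settings)
            res = model.simulate(regimen, t_out_h=list(STEADY_STATE_WINDOW_H))
        except Exception as exc:              # record missing, keep scanning
            warnings.warn(f"scan point {name} x{m:.2f} failed: {exc}")
            for o in organs:
                records[o].append(np.nan)
            plasma.append(np.nan)
            continue
        for o in organs:
            records[o].append(res.auc_intracellular_unbound(o, STEADY_STATE_WINDOW_H))
        plasma.append(res.auc_plasma(STEADY_STATE_WINDOW_H))

    auc = pd.DataFrame(records, index=mults).T
    return SensitivityScan(parameter=name, multipliers=mults, auc=auc,
                           plasma_auc=pd.Series(plasma, index=mults),
                           reference_index=ref_idx)


def classify_response(scan: SensitivityScan, organ: str) -> ShapeClassification:
    """Classify one organ's response: near-linear or interior extremum.

    Near-linear means the straight-line fit over the grid has R² ≥ 0.99.
    Otherwise an interior extremum is located from the sign pattern of
    the first differences (confirmed by the discrete second difference).
    """
    y = scan.auc.loc[organ].to_numpy(float)
    x = scan.multipliers
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("scan too sparse to classify")

    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 >= 0.99:
        return ShapeClassification("near-linear", None, r2)

    i_max = int(np.argmax(y))
    i_min = int(np.argmin(y))
    d2 = np.diff(y, 2)
    if 0 < i_max < y.size - 1 and d2[i_max - 1] < 0:
        return ShapeClassification("interior-maximum", float(x[i_max]), r2)
    if 0 < i_min < y.size - 1 and d2[i_min - 1] > 0:
        return ShapeClassification("interior-minimum", float(x[i_min]), r2)
    return ShapeClassification("near-linear", None, r2)
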
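"""Hepatic-impairment scaling of the CES1 metabolic pathway.

Two complementary pathways are implemented:

* **Empirical (NCI-ODWG)** — the CES1 specific clearance is an empirical
  power law of the total-bilirubin plasma concentration,

      CL_spec(TBIL) = CL_spec,median * (TBIL / TBIL_median)^(-alpha),

  anchored at the median TBIL of patients with normal hepatic function.
  The exponent ``alpha`` follows from the CL_spec ratio calibrated on
  single-dose data in moderate hepatic impairment; only CL_spec changes
  across severity groups (all CES1 pools scale together), every other
  parameter stays at its normal value.

* **Mechanistic (Child-Pugh)** — prior physiological knowledge about
  cirrhosis: reduced functional liver volume, portosystemic flow
  changes, reduced renal flow, raised unbound fraction, and optionally a
  reduced hepatic CES1 abundance, applied as multipliers to the
  reference individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import (
    AbcSmcConfig,
    CalibrationContext,
    ObservedCohort,
    ParticlePopulation,
    PriorSpec,
    abc_smc,
)
from .physiology import (
    HepaticVariant,
    ReferenceIndividual,
    apply_hepatic_variant,
    child_pugh_variants,
)

__all__ = [
    "PowerLawModel",
    "HepaticGroup",
    "clspec_from_tbil",
    "solve_alpha",
    "nci_odwg_groups",
    "calibrate_mhi_clspec",
    "child_pugh_pathway",
    "DEFAULT_ALPHA",
    "DEFAULT_GROUP_TBIL",
]

#: Power-law exponent relating CL_spec to TBIL (re-derivable via
#: :func:`calibrate_mhi_clspec` + :func:`solve_alpha`).
DEFAULT_ALPHA = 0.316

#: Median TBIL (µM) per NCI-ODWG severity group.
DEFAULT_GROUP_TBIL = {
    "NHF": 6.8,
    "mild": 21.25,
    "MHI": 41.9,
    "severe60": 60.0,
    "severe120": 120.0,
}


@dataclass(frozen=True)
class PowerLawModel:
    """CL_spec(TBIL) power law anchored at normal hepatic function."""

    clspec_median: float              # L/min/µmol, normal hepatic function
    tbil_median: float                # µM
    alpha: float

    def __post_init__(self) -> None:
        if self.clspec_median <= 0 or self.tbil_median <= 0 or self.alpha < 0:
            raise ValueError("power-law anchors must be > 0 and alpha >= 0")


@dataclass(frozen=True)
class HepaticGroup:
    """NCI-ODWG severity group with its median TBIL (µM)."""

    label: str
    tbil: float

    def __post_init__(self) -> None:
        if self.tbil <= 0:
            raise ValueError("TBIL must be > 0")


def clspec_from_tbil(model: PowerLawModel, tbil: float) -> float:
    """CL_spec at a given total-bilirubin level; decreasing in TBIL."""
    if tbil <= 0:
        raise ValueError("TBIL must be > 0")
    return model.clspec_median * (tbil / model.tbil_median) ** (-model.alpha)


def solve_alpha(nhf: tuple[float, float], impaired: tuple[float, float]) -> float:
    """Exponent from two (TBIL, CL_spec) points; inverse of the power law.

    ``alpha = ln(CL_nhf / CL_imp) / ln(TBIL_imp / TBIL_nhf)``.
    """
    tbil_n, cl_n = nhf
    tbil_i, cl_i = impaired
    if min(tbil_n, cl_n, tbil_i, cl_i) <= 0:
        raise ValueError("TBIL and CL_spec values must be > 0")
    if tbil_n == tbil_i:
        raise ValueError("TBIL values must be distinct")
    return math.log(cl_n / cl_i) / math.log(tbil_i / tbil_n)


def nci_odwg_groups(tbil: dict[str, float] | None = None) -> list[HepaticGroup]:
    """The five severity groups ordered by increasing TBIL."""
    values = dict(DEFAULT_GROUP_TBIL)
    if tbil:
        values.update(tbil)
    groups = [HepaticGroup(label, v) for label, v in values.items()]
    return sorted(groups, key=lambda g: g.tbil)


def calibrate_mhi_clspec(mhi_cohort: ObservedCohort,
                         context: CalibrationContext,
                         config: AbcSmcConfig,
                         prior_cv: float = 1.0) -> ParticlePopulation:
    """Posterior for CL_spec in the moderate-impairment group.

    Re-runs the ABC-SMC machinery with only CL_spec free (prior centred
    on the normal-function value, CV 100%) against the single-dose MHI
    cohort; no urine constraint applies.  The final-generation posterior
    feeds :func:`solve_alpha`.
    """
    priors = [PriorSpec("cl_spec", context.base_drug.cl_spec, prior_cv)]
    pops = abc_smc([mhi_cohort], priors, None, None, config, context)
    return pops[-1]


def child_pugh_pathway(ind: ReferenceIndividual, grade: str,
                       ces1_reduction: float | None = None,
                       variants: dict[str, HepaticVariant] | None = None,
                       ) -> ReferenceIndividual:
    """Simulation-ready individual for a Child-Pugh grade.

    Applies the grade's physiological multipliers; ``ces1_reduction``
    additionally divides the hepatic CES1 abundance (e.g. 3.3 for the
    reduction reported in end-stage liver disease).
    """
    variants = variants or child_pugh_variants()
    if grade not in variants:
        raise ValueError(f"unknown Child-Pugh grade: {grade!r} "
                         f"(expected one of {sorted(variants)})")
    out = apply_hepatic_variant(ind, variants[grade])
    if ces1_reduction is not None:
        if ces1_reduction <= 0:
            raise ValueError("ces1_reduction must be > 0")
        liver = out.organs["liver"]
        out = out.replace_organ(
            "liver",
            ces1_relative_abundance=liver.ces1_relative_abundance / ces1_reduction)
    return out
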
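"""Anchoring of the absolute CES1 abundance scale.

The CES1 reference concentration (µmol enzyme per L liver intracellular
volume) is the one absolute scale of the metabolic pathway that cannot be
taken from drug-specific data: only the product
``CL_spec × [CES1]`` is identifiable from plasma kinetics.  The package
anchors it so that the fully calibrated model reproduces the
normal-hepatic-function steady-state plasma exposure baseline
(300 mg once daily, AUC over the 24 h after the 28th dose), the same
baseline every downstream exposure ratio is reported against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .engine import DoseRegimen, DrugParameters, FormulationParameters, PBPKModel, SolverSettings
from .physiology import ReferenceIndividual

__all__ = ["anchor_ces1_reference", "NHF_AUC_SS_BASELINE", "REFERENCE_REGIMEN"]

#: Normal-hepatic-function steady-state plasma AUC baseline, µM·min
#: (300 mg QD, 24 h window after the 28th daily dose).
NHF_AUC_SS_BASELINE = 4155.0

REFERENCE_REGIMEN = DoseRegimen.qd(300.0, 28)
REFERENCE_WINDOW_H = (648.0, 672.0)


def anchor_ces1_reference(drug: DrugParameters,
                          individual: ReferenceIndividual,
                          formulation: FormulationParameters | None = None,
                          settings: SolverSettings | None = None,
                          target_auc_ss: float = NHF_AUC_SS_BASELINE,
                          bracket: tuple[float, float] = (2.0, 5000.0),
                          rtol: float = 1e-6) -> ReferenceIndividual:
    """Return the individual with the CES1 reference concentration anchored.

    Root-finds (on a log scale; plasma AUC_ss is monotone decreasing in
    the enzyme scale) the liver CES1 concentration at which the 300 mg QD
    steady-state plasma AUC equals ``target_auc_ss``.
    """

    def auc_at(log_ref: float) -> float:
        ind = dataclasses.replace(individual,
                                  ces1_reference_concentration=float(np.exp(log_ref)))
        model = PBPKModel(drug, ind, formulation, settings)
        res = model.simulate(REFERENCE_REGIMEN,
                             t_out_h=list(REFERENCE_WINDOW_H))
        return res.auc_plasma(REFERENCE_WINDOW_H)

    log_ref = brentq(lambda x: auc_at(x) - target_auc_ss,
                     np.log(bracket[0]), np.log(bracket[1]), rtol=rtol)
    return dataclasses.replace(individual,
                               ces1_reference_concentration=float(np.exp(log_ref)))
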
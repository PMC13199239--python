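"""Exposure simulation across hepatic groups and model-based dose selection.

Exposures are simulated at steady state (24 h after the 28th daily dose)
for every severity group; because the model is exactly linear in dose,
the dose grid is filled by proportional scaling of one simulation per
group.  Dose selection targets a plasma AUC_ss within ±20% of the
normal-hepatic-function reference at the full 300 mg dose.  Three rules
are available: ``plasma-max`` (largest admissible grid dose by plasma
AUC), ``all-compartments`` (every monitored tissue must also stay inside
the window) and ``harmonized-severe`` (the two severe groups share the
lower of their admissible doses, the convention used in practice when a
single label dose covers all severe patients).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    DoseRegimen,
    DrugParameters,
    FormulationParameters,
    PBPKModel,
    SolverSettings,
    pk_metrics,
)
from .hepatic import HepaticGroup, PowerLawModel, clspec_from_tbil, nci_odwg_groups
from .physiology import ReferenceIndividual

__all__ = [
    "ExposureTable",
    "DoseRecommendation",
    "exposure_grid",
    "select_dose",
    "adjusted_exposure_report",
    "DEFAULT_DOSE_GRID",
    "DEFAULT_MONITORED_TISSUES",
]

DEFAULT_DOSE_GRID = (100.0, 150.0, 200.0, 250.0, 300.0)
DEFAULT_MONITORED_TISSUES = ("liver", "kidney", "bone", "gonads", "muscle",
                             "heart", "lung", "brain", "small_intestine")
STEADY_STATE_WINDOW_H = (648.0, 672.0)
SELECTION_RULES = ("plasma-max", "all-compartments", "harmonized-severe")


@dataclass
class ExposureTable:
    """Long-format exposure table with the reference definition attached."""

    data: pd.DataFrame                # group, tbil, dose_mg, compartment, metric, value, ratio
    reference_group: str
    reference_dose: float

    def ratio(self, group: str, dose: float, compartment: str = "plasma",
              metric: str = "auc_ss") -> float:
        df = self.data
        row = df[(df.group == group) & (df.dose_mg == dose)
                 & (df.compartment == compartment) & (df.metric == metric)]
        if row.empty:
            raise KeyError((group, dose, compartment, metric))
        return float(row["ratio"].iloc[0])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    @property
    def doses(self) -> list[float]:
        return sorted(set(self.data["dose_mg"]))


@dataclass(frozen=True)
class DoseRecommendation:
    """Selected dose for one severity group."""

    group: str
    dose_mg: float | None             # None when no grid dose is admissible
    plasma_auc_ratio: float | None
    max_tissue_deviation: float | None
    rule: str

    @property
    def admissible(self) -> bool:
        return self.dose_mg is not None


def exposure_grid(groups: Sequence[HepaticGroup] | None,
                  doses: Sequence[float] | None,
                  drug: DrugParameters,
                  individual: ReferenceIndividual,
                  formulation: FormulationParameters | None = None,
                  settings: SolverSettings | None = None,
                  power_law: PowerLawModel | None = None,
                  tissues: Sequence[str] = DEFAULT_MONITORED_TISSUES,
                  reference: tuple[str, float] = ("NHF", 300.0),
                  ) -> ExposureTable:
    """Steady-state exposures per group × dose, ratioed to the reference.

    One 28-day simulation per group at the reference dose; the rest of
    the dose grid follows from exact dose proportionality.  Metrics:
    plasma total AUC_ss and Cmax, and intracellular unbound AUC_ss per
    monitored tissue, all over the 24 h after the 28th dose.
    """
    groups = list(groups) if groups is not None else nci_odwg_groups()
    doses = tuple(doses) if doses is not None else DEFAULT_DOSE_GRID
    if power_law is None:
        nhf_tbil = next(g.tbil for g in groups if g.label == reference[0])
        power_law = PowerLawModel(drug.cl_spec, nhf_tbil, 0.316)
    ref_group, ref_dose = reference
    regimen = DoseRegimen.qd(ref_dose, 28)

    rows = []
    for group in groups:
        drug_g = drug.replace(cl_spec=clspec_from_tbil(power_law, group.tbil))
        model = PBPKModel(drug_g, individual, formulation, settings)
        res = model.simulate(regimen, dense_windows_h=[STEADY_STATE_WINDOW_H])
        metrics = pk_metrics(res, "plasma", STEADY_STATE_WINDOW_H)
        base = {"plasma": {"auc_ss": metrics.auc, "cmax": metrics.cmax}}
        for tissue in tissues:
            base[tissue] = {"auc_ss": res.auc_intracellular_unbound(
                tissue, STEADY_STATE_WINDOW_H)}
        for dose in doses:
            scale = dose / ref_dose      # exact linearity of the model
            for compartment, metric_map in base.items():
                for metric, value in metric_map.items():
                    rows.append({
                        "group": group.label, "tbil": group.tbil,
                        "dose_mg": dose, "compartment": compartment,
                        "metric": metric, "value": value * scale,
                    })
    df = pd.DataFrame(rows)
    ref_values = (df[(df.group == ref_group) & (df.dose_mg == ref_dose)]
                  .set_index(["compartment", "metric"])["value"])
    df["ratio"] = df.apply(
        lambda r: r["value"] / ref_values[(r["compartment"], r["metric"])], axis=1)
    return ExposureTable(data=df, reference_group=ref_group, reference_dose=ref_dose)


def _admissible_doses(table: ExposureTable, group: str, tolerance: float,
                      grid: Sequence[float], tissues_too: bool,
                      tissues: Sequence[str]) -> list[float]:
    lo, hi = 1.0 - tolerance, 1.0 + tolerance
    out = []
    for dose in grid:
        ratios = [table.ratio(group, dose, "plasma", "auc_ss")]
        if tissues_too:
            ratios += [table.ratio(group, dose, t, "auc_ss") for t in tissues
                       if not table.data[(table.data.compartment == t)].empty]
        if all(lo - 1e-12 <= r <= hi + 1e-12 for r in ratios):
            out.append(dose)
    return out


def select_dose(table: ExposureTable, rule: str = "plasma-max",
                tolerance: float = 0.20,
                grid: Sequence[float] | None = None,
                tissues: Sequence[str] = DEFAULT_MONITORED_TISSUES,
                severe_labels: Sequence[str] = ("severe60", "severe120"),
                ) -> list[DoseRecommendation]:
    """Per-group dose recommendations under the chosen selection rule."""
    if rule not in SELECTION_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {SELECTION_RULES}")
    grid = sorted(grid if grid is not None else table.doses)
    tissues_too = rule == "all-compartments"

    chosen: dict[str, float | None] = {}
    for group in table.groups:
        adm = _admissible_doses(table, group, tolerance, grid, tissues_too, tissues)
        chosen[group] = max(adm) if adm else None

    if rule == "harmonized-severe":
        severe = [g for g in severe_labels if g in chosen and chosen[g] is not None]
        if severe:
            shared = min(chosen[g] for g in severe)
            for g in severe:
                chosen[g] = shared

    out = []
    for group in table.groups:
        dose = chosen[group]
        if dose is None:
            out.append(DoseRecommendation(group, None, None, None, rule))
            continue
        plasma = table.ratio(group, dose, "plasma", "auc_ss")
        devs = [abs(table.ratio(group, dose, t, "auc_ss") - 1.0)
                for t in tissues
                if not table.data[table.data.compartment == t].empty]
        out.append(DoseRecommendation(group, dose, plasma,
                                      max(devs) if devs else None, rule))
    return out


@dataclass
class AdjustedExposureReport:
    """Per-group tissue exposure ratios under the adjusted doses."""

    tissue_ratios: pd.DataFrame       # group, dose_mg, compartment, ratio, within_tolerance
    bone_to_gonads: pd.DataFrame      # group, dose_mg, ratio


def adjusted_exposure_report(recommendations: Sequence[DoseRecommendation],
                             table: ExposureTable,
                             tolerance: float = 0.20,
                             tissues: Sequence[str] = DEFAULT_MONITORED_TISSUES,
                             ) -> AdjustedExposureReport:
    """Exposure ratios at the recommended doses, plus bone:gonads ratios."""
    rows, bg = [], []
    for rec in recommendations:
        if not rec.admissible:
            continue
        comps = ["plasma", *[t for t in tissues
                             if not table.data[table.data.compartment == t].empty]]
        for comp in comps:
            ratio = table.ratio(rec.group, rec.dose_mg, comp, "auc_ss")
            rows.append({"group": rec.group, "dose_mg": rec.dose_mg,
                         "compartment": comp, "ratio": ratio,
                         "within_tolerance": abs(ratio - 1.0) <= tolerance + 1e-12})
        df = table.data
        get = lambda comp: float(df[(df.group == rec.group)
                                    & (df.dose_mg == rec.dose_mg)
                                    & (df.compartment == comp)
                                    & (df.metric == "auc_ss")]["value"].iloc[0])
        try:
            bg.append({"group": rec.group, "dose_mg": rec.dose_mg,
                       "ratio": get("bone") / get("gonads")})
        except IndexError:
            pass
    return AdjustedExposureReport(tissue_ratios=pd.DataFrame(rows),
                                  bone_to_gonads=pd.DataFrame(bg))
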
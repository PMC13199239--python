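"""Synthetic aggregated cohorts for end-to-end testing of the pipeline.

The clinical inputs of this analysis are aggregated mean
concentration–time profiles digitized from literature plots, plus one
urinary mass-balance fraction; none are deposited in reusable form.
This module emulates their statistical structure: a known ground-truth
parameter set is simulated, sampled on a realistic sparse schedule and
perturbed with multiplicative lognormal noise (log-mean 0) applied to
the aggregated means — matching what the calibration consumes.  No
inter-individual variability layer is simulated, because the real data
are cohort means as well.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calibration import MassBalanceConstraint, ObservedCohort, write_cohorts
from .engine import (
    DoseRegimen,
    DrugParameters,
    FormulationParameters,
    PBPKModel,
    SolverSettings,
    load_drug,
    load_formulation,
    urinary_unchanged_fraction,
)
from .hepatic import DEFAULT_ALPHA, DEFAULT_GROUP_TBIL
from .physiology import ReferenceIndividual, load_reference_individual

__all__ = [
    "NoiseModel",
    "CohortDesign",
    "generate_cohort",
    "apply_noise",
    "generate_mass_balance",
    "scenario",
    "scenario_bundle",
    "SCENARIO_NAMES",
    "DEFAULT_DAY1_TIMES",
]

#: Sparse day-1 sampling schedule (hours post dose).
DEFAULT_DAY1_TIMES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
#: Day-21 peak-and-trough occasions for QD designs (hours from start).
DEFAULT_DAY21_TIMES = (483.0, 504.0)

SCENARIO_NAMES = ("calibration_210qd", "multi_dose_60_80_210",
                  "mhi_single_300", "validation_300sd_300qd_200qd")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise on aggregated mean concentrations."""

    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("CV must be >= 0")

    @property
    def sigma(self) -> float:
        """Log-scale SD giving exactly the requested coefficient of variation."""
        return float(np.sqrt(np.log1p(self.cv ** 2)))


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design for one synthetic cohort."""

    dose_mg: float
    regimen: str                      # "QD" or "SD"
    times_h: tuple[float, ...]
    study: str = "synthetic"
    n: int | None = 12                # cosmetic cohort size
    n_days: int | None = None         # explicit QD horizon (default: cover times)

    def dose_regimen(self) -> DoseRegimen:
        if self.regimen == "SD":
            return DoseRegimen.single(self.dose_mg)
        n_days = self.n_days or max(1, int(np.ceil(max(self.times_h) / 24.0)))
        return DoseRegimen.qd(self.dose_mg, n_days)


def qd_design(dose_mg: float, study: str | None = None) -> CohortDesign:
    """Default repeated-dose design: day-1 curve plus day-21 peak/trough."""
    return CohortDesign(dose_mg, "QD", DEFAULT_DAY1_TIMES + DEFAULT_DAY21_TIMES,
                        study=study or f"{dose_mg:g}mg_QD")


def sd_design(dose_mg: float, study: str | None = None) -> CohortDesign:
    times = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)
    return CohortDesign(dose_mg, "SD", times, study=study or f"{dose_mg:g}mg_SD")


def apply_noise(values: np.ndarray, noise: NoiseModel,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply i.i.d. multiplicative lognormal noise (log-mean 0)."""
    values = np.asarray(values, float)
    if noise.cv == 0:
        return values.copy()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return values * np.exp(noise.sigma * rng.standard_normal(values.shape))


def generate_cohort(design: CohortDesign,
                    drug: DrugParameters,
                    individual: ReferenceIndividual,
                    formulation: FormulationParameters | None = None,
                    noise: NoiseModel = NoiseModel(),
                    settings: SolverSettings | None = None) -> ObservedCohort:
    """Simulate the truth model at the design times and add noise.

    Reproducible from the noise seed; CV = 0 returns the engine output
    exactly.
    """
    regimen = design.dose_regimen()
    if max(design.times_h) > regimen.last_dose_h + 24.0 and design.regimen == "QD":
        raise ValueError("sampling times beyond the simulated horizon")
    model = PBPKModel(drug, individual, formulation, settings)
    res = model.simulate(regimen, t_out_h=design.times_h)
    conc = apply_noise(res.venous_plasma(), noise)
    return ObservedCohort(study=design.study, dose_mg=design.dose_mg,
                          regimen=design.regimen, times_h=design.times_h,
                          conc_uM=tuple(conc), n=design.n)


def generate_mass_balance(drug: DrugParameters,
                          individual: ReferenceIndividual,
                          formulation: FormulationParameters | None = None,
                          window_h: tuple[float, float] | None = None,
                          halfwidth: float = 0.40,
                          settings: SolverSettings | None = None,
                          horizon_h: float = 504.0) -> MassBalanceConstraint:
    """Urinary unchanged-fraction observation from the truth model.

    Simulates repeated 300 mg daily dosing to the stated horizon and
    reports the cumulative unchanged urinary fraction of the dose as the
    expected value, with the standard ±40% (relative) window.
    """
    n_days = max(1, int(np.ceil(horizon_h / 24.0)))
    model = PBPKModel(drug, individual, formulation, settings)
    res = model.simulate(DoseRegimen.qd(300.0, n_days), t_out_h=[horizon_h])
    fe = urinary_unchanged_fraction(res, window_h)
    return MassBalanceConstraint(expected_fraction=fe, halfwidth=halfwidth,
                                 window_h=window_h)


@dataclass
class Scenario:
    """A packaged fixture set: noisy cohorts plus their ground truth."""

    name: str
    cohorts: list[ObservedCohort]
    truth_drug: DrugParameters
    individual: ReferenceIndividual
    formulation: FormulationParameters
    constraint: MassBalanceConstraint | None
    noise: NoiseModel


def scenario(name: str, seed: int = 2024, noise_cv: float = 0.15,
             settings: SolverSettings | None = None) -> Scenario:
    """Build a named fixture scenario in memory (bit-reproducible by seed)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    drug = load_drug()
    formulation = load_formulation()
    individual = load_reference_individual()
    noise = NoiseModel(cv=noise_cv, seed=seed)
    rng = np.random.default_rng(seed)

    if name == "calibration_210qd":
        designs = [qd_design(210.0)]
        truth = drug
        constraint = generate_mass_balance(truth, individual, formulation,
                                           settings=settings)
    elif name == "multi_dose_60_80_210":
        designs = [qd_design(60.0), qd_design(80.0), qd_design(210.0)]
        truth = drug
        constraint = generate_mass_balance(truth, individual, formulation,
                                           settings=settings)
    elif name == "mhi_single_300":
        designs = [sd_design(300.0, study="MHI_300mg_SD")]
        # moderate hepatic impairment ground truth: CL_spec scaled by the
        # power law at the MHI median TBIL
        scale = (DEFAULT_GROUP_TBIL["MHI"] / DEFAULT_GROUP_TBIL["NHF"]) ** (-DEFAULT_ALPHA)
        truth = drug.replace(cl_spec=drug.cl_spec * scale)
        constraint = None
    else:  # validation_300sd_300qd_200qd
        designs = [sd_design(300.0), qd_design(300.0), qd_design(200.0)]
        truth = drug
        constraint = None

    cohorts = []
    for design in designs:
        sub_noise = NoiseModel(cv=noise_cv, seed=int(rng.integers(2 ** 31)))
        cohorts.append(generate_cohort(design, truth, individual, formulation,
                                       sub_noise, settings))
    return Scenario(name=name, cohorts=cohorts, truth_drug=truth,
                    individual=individual, formulation=formulation,
                    constraint=constraint, noise=noise)


def scenario_bundle(name: str, out_dir: str | Path, seed: int = 2024,
                    noise_cv: float = 0.15) -> Path:
    """Write a scenario to disk: cohort CSV, truth YAML, seed record."""
    sc = scenario(name, seed=seed, noise_cv=noise_cv)
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    write_cohorts(sc.cohorts, out / "cohorts.csv")
    truth = {"drug": dataclasses.asdict(sc.truth_drug),
             "formulation": dataclasses.asdict(sc.formulation)}
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    if sc.constraint is not None:
        (out / "urine.yaml").write_text(yaml.safe_dump({
            "expected_fraction": sc.constraint.expected_fraction,
            "halfwidth": sc.constraint.halfwidth,
            "mode": sc.constraint.mode}, sort_keys=False))
    (out / "seeds.json").write_text(json.dumps(
        {"seed": seed, "noise_cv": noise_cv, "scenario": name}, indent=2))
    return out
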
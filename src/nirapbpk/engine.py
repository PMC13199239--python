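"""Whole-body PBPK ODE engine for an orally dosed ionizable weak base.

Model structure
---------------
Oral dosing enters a gastrointestinal tract with Weibull capsule
dissolution, first-order gastric emptying, a single small-intestine
transit segment (unabsorbed drug exits to feces) and permeability-limited
absorption into the intestinal intracellular space (enterocytes), where
gut-wall CES1 metabolism takes a first pass.  Every organ is split into a
vascular (plasma), an interstitial and an intracellular sub-compartment.
Organs are perfused in parallel from arterial plasma; the splanchnic
organs drain through the portal vein into the liver; the lung sits in
series on the venous return.  Vascular–interstitial exchange is fast
(perfusion-limited); interstitial–intracellular exchange is
charge-dependent: the neutral species permeates with a lipophilicity
derived permeability, the charged species with a small fraction of it,
which produces pH-driven ion trapping of the base inside cells.
Elimination is CES1-mediated first-order metabolism of intracellular
unbound drug plus renal clearance of total plasma drug in the kidney.

All processes are first order, so the whole system is linear in amounts;
within one dosing interval it is linear time-invariant apart from the
Weibull dissolution hazard.  The integrator exploits this: the response
to each dose is computed once with a stiff (BDF) solve over a forcing
window that outlasts dissolution, and the remainder of every interval is
propagated exactly with a cached matrix exponential.  Intervals whose
output samples are requested are integrated densely instead.

Internal units: µmol, L, min.  User-facing units: hours, µM, µM·min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .physiology import OrganSpec, ReferenceIndividual, ces1_amounts

__all__ = [
    "DrugParameters",
    "FormulationParameters",
    "DoseRegimen",
    "SolverSettings",
    "SimulationResult",
    "PKMetrics",
    "ExchangeRates",
    "PBPKModel",
    "fraction_neutral",
    "weibull_dissolved_fraction",
    "cellular_permeability",
    "intracellular_binding",
    "partition_coefficient",
    "cellular_exchange_rates",
    "pk_metrics",
    "urinary_unchanged_fraction",
    "load_drug",
    "load_formulation",
    "IntegrationError",
]

LN2 = float(np.log(2.0))

# Tissue-affinity coefficients of the composition-based partitioning
# scheme.  Affinities of the neutral species scale with the octanol:water
# coefficient; charged-species affinities are scaled down for the neutral
# lipid phase and nearly preserved for phospholipid membranes, whose
# headgroups retain cations.  The membrane-affinity intercept is a
# package-level calibration constant (see docs/methods.md).
MEMBRANE_AFFINITY_LOG_SLOPE = 1.0
MEMBRANE_AFFINITY_LOG_INTERCEPT = 0.135
MEMBRANE_ION_FACTOR = 0.9
NEUTRAL_LIPID_ION_FACTOR = 1e-3
PROTEIN_AFFINITY = 2.0
# Neutral-species transmembrane permeability correlation, dm/min.  The
# effective in-vivo slope is well below the octanol:water slope because
# unstirred water layers and membrane saturation blunt the lipophilicity
# dependence of transcellular transport.
CELL_PERMEABILITY_LOG_SLOPE = 0.40
CELL_PERMEABILITY_LOG_INTERCEPT = -3.428


class IntegrationError(RuntimeError):
    """ODE integration failed or produced an invalid state."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific parameters of the PBPK model.

    Units: ``mw`` g/mol; ``p_int`` dm/min; ``cl_ren`` L/min/kg;
    ``cl_spec`` L/min/µmol CES1; the rest dimensionless.
    ``ionic_permeability_factor`` is the charged:neutral membrane
    permeability ratio of the charge-dependent cellular exchange model.
    """

    mw: float
    fu: float
    logP: float
    pKa: float
    p_int: float
    cl_ren: float
    cl_spec: float
    ionic_permeability_factor: float = 8.0e-4

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("MW must be > 0")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")
        if min(self.p_int, self.cl_ren, self.cl_spec) < 0:
            raise ValueError("permeability and clearances must be >= 0")
        if not 0 <= self.ionic_permeability_factor <= 1:
            raise ValueError("ionic_permeability_factor must be in [0, 1]")

    def replace(self, **changes) -> "DrugParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class FormulationParameters:
    """Oral formulation: Weibull dissolution or an already-dissolved dose.

    ``dissolution_time_50pct`` is the time to 50% dissolved (minutes),
    the PK-Sim convention; set ``convention="t63"`` to interpret the time
    parameter as the 63.2% characteristic time instead.  ``form`` may be
    ``"capsule"`` (Weibull dissolution in the stomach lumen) or
    ``"solution"`` (dose enters the intestinal lumen dissolved).
    """

    dissolution_time_50pct: float = 30.0
    dissolution_shape: float = 2.0
    form: str = "capsule"
    convention: str = "t50"

    def __post_init__(self) -> None:
        if self.dissolution_time_50pct <= 0 or self.dissolution_shape <= 0:
            raise ValueError("dissolution parameters must be > 0")
        if self.form not in ("capsule", "solution"):
            raise ValueError(f"unknown form: {self.form}")
        if self.convention not in ("t50", "t63"):
            raise ValueError(f"unknown Weibull convention: {self.convention}")


@dataclass(frozen=True)
class DoseRegimen:
    """Dose (mg per administration) and administration times (hours)."""

    dose_mg: float
    times_h: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose must be > 0")
        t = np.asarray(self.times_h, float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("administration times must be strictly increasing")

    @classmethod
    def qd(cls, dose_mg: float, n_days: int) -> "DoseRegimen":
        return cls(dose_mg, tuple(24.0 * k for k in range(n_days)),
                   label=f"{dose_mg:g} mg QD x{n_days}")

    @classmethod
    def single(cls, dose_mg: float) -> "DoseRegimen":
        return cls(dose_mg, (0.0,), label=f"{dose_mg:g} mg SD")

    @property
    def last_dose_h(self) -> float:
        return self.times_h[-1]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the ODE engine.

    ``forcing_window_min`` is the per-dose span integrated with the stiff
    solver before the residual undissolved mass (~2^-256 of the dose for
    the default capsule) is folded into the dissolved pool and the
    interval remainder is propagated by matrix exponential.
    ``renal_on_unbound`` switches renal clearance from total to unbound
    kidney plasma concentration.  ``cellular_permeability`` overrides the
    lipophilicity-derived neutral-species permeability (dm/min).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    forcing_window_min: float = 480.0
    dense_resolution_min: float = 1.0
    vi_exchange_factor: float = 20.0
    renal_on_unbound: bool = False
    cellular_permeability: float | None = None


@dataclass(frozen=True)
class PKMetrics:
    """Cmax (µM), Tmax (h) and AUC (µM·min) over a stated window."""

    cmax: float
    tmax_h: float
    auc: float
    window_h: tuple[float, float]


# ---------------------------------------------------------------------------
# closed-form building blocks


def fraction_neutral(pKa: float, pH: float | np.ndarray) -> float | np.ndarray:
    """Neutral fraction of a monoprotic base (Henderson–Hasselbalch)."""
    pH = np.asarray(pH, float)
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH outside [0, 14]")
    out = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return float(out) if out.ndim == 0 else out


def weibull_dissolved_fraction(t: float | np.ndarray,
                               f: FormulationParameters) -> float | np.ndarray:
    """Fraction of the dose dissolved at time ``t`` (minutes) after intake."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    scale = LN2 if f.convention == "t50" else 1.0
    out = 1.0 - np.exp(-scale * (t / f.dissolution_time_50pct) ** f.dissolution_shape)
    return float(out) if out.ndim == 0 else out


def _dissolution_hazard(age: float, f: FormulationParameters) -> float:
    """Instantaneous dissolution rate coefficient (1/min) at dose age."""
    if age <= 0:
        return 0.0 if f.dissolution_shape >= 1 else np.inf
    scale = LN2 if f.convention == "t50" else 1.0
    s, td = f.dissolution_shape, f.dissolution_time_50pct
    return scale * s / td * (age / td) ** (s - 1.0)


def cellular_permeability(drug: DrugParameters) -> float:
    """Neutral-species transmembrane permeability (dm/min) from logP."""
    return 10.0 ** (CELL_PERMEABILITY_LOG_SLOPE * drug.logP
                    + CELL_PERMEABILITY_LOG_INTERCEPT)


def _phase_affinities(drug: DrugParameters, pH: float) -> tuple[float, float, float]:
    """(neutral lipid, phospholipid, protein) affinities at the given pH."""
    k_ow = 10.0 ** drug.logP
    k_mem = 10.0 ** (MEMBRANE_AFFINITY_LOG_SLOPE * drug.logP
                     + MEMBRANE_AFFINITY_LOG_INTERCEPT)
    fn = fraction_neutral(drug.pKa, pH)
    k_nl = fn * k_ow + (1.0 - fn) * k_ow * NEUTRAL_LIPID_ION_FACTOR
    k_pl = fn * k_mem + (1.0 - fn) * k_mem * MEMBRANE_ION_FACTOR
    return k_nl, k_pl, PROTEIN_AFFINITY


def intracellular_binding(drug: DrugParameters, organ: OrganSpec) -> float:
    """Total:unbound concentration ratio inside the cells of an organ.

    Composition-based: aqueous drug partitions into neutral lipid,
    phospholipid membranes and protein according to lipophilicity and the
    ionization state at the intracellular pH.
    """
    comp = organ.composition
    k_nl, k_pl, k_pr = _phase_affinities(drug, organ.pH_intracellular)
    return (comp.water + comp.neutral_lipid * k_nl
            + comp.phospholipid * k_pl + comp.protein * k_pr)


@dataclass(frozen=True)
class ExchangeRates:
    """Interstitial↔intracellular exchange clearances (L/min)."""

    influx_clearance: float
    efflux_clearance: float

    @property
    def trap_ratio(self) -> float:
        """Steady-state intracellular:interstitial unbound ratio."""
        return self.influx_clearance / self.efflux_clearance


def _effective_permeability(drug: DrugParameters, pH: float,
                            p_neutral: float,
                            kappa: float | None = None) -> float:
    fn = fraction_neutral(drug.pKa, pH)
    if kappa is None:
        kappa = drug.ionic_permeability_factor
    return p_neutral * (fn + kappa * (1.0 - fn))


def cellular_exchange_rates(drug: DrugParameters, organ: OrganSpec,
                            surface_area_per_volume: float = 2000.0,
                            p_neutral: float | None = None) -> ExchangeRates:
    """Charge-dependent cellular influx/efflux exchange clearances.

    The effective permeability on each side weights the neutral-species
    permeability by the neutral fraction at the donor-side pH plus
    ``ionic_permeability_factor`` times the charged fraction; with zero
    ionic permeability the steady-state unbound ratio reduces to the
    closed-form pH ion-trap ratio
    ``(1 + 10^(pKa-pH_ic)) / (1 + 10^(pKa-pH_is))``.
    """
    if p_neutral is None:
        p_neutral = cellular_permeability(drug)
    if organ.cell_surface_area_per_volume is not None:
        surface_area_per_volume = organ.cell_surface_area_per_volume
    kappa = organ.ionic_permeability_factor
    area = surface_area_per_volume * organ.intracellular_volume
    p_in = _effective_permeability(drug, organ.pH_interstitial, p_neutral, kappa)
    p_out = _effective_permeability(drug, organ.pH_intracellular, p_neutral, kappa)
    return ExchangeRates(p_in * area, p_out * area)


def partition_coefficient(drug: DrugParameters, organ: OrganSpec,
                          plasma_pH: float = 7.4) -> float:
    """Total tissue:plasma partition coefficient at distribution equilibrium.

    Combines the vascular, interstitial (unbound) and intracellular
    (composition-bound, pH ion-trapped) sub-compartments of the organ.
    Deterministic in the drug parameters and tissue composition.
    """
    del plasma_pH  # plasma reference is total concentration; fu covers binding
    bf = intracellular_binding(drug, organ)
    ratio = cellular_exchange_rates(drug, organ).trap_ratio
    return (organ.plasma_fraction
            + drug.fu * (organ.interstitial_fraction
                         + organ.intracellular_fraction * bf * ratio))


# ---------------------------------------------------------------------------
# state indexing


class _Index:
    """State-vector layout of the whole-body model."""

    def __init__(self, organs: Sequence[str]):
        self.organs = list(organs)
        self.st_solid, self.si_solid, self.st_diss, self.si_diss = 0, 1, 2, 3
        self.art, self.ven, self.mucosa = 4, 5, 6
        base = 7
        self.vas = {o: base + 3 * i for i, o in enumerate(self.organs)}
        self.ist = {o: base + 3 * i + 1 for i, o in enumerate(self.organs)}
        self.cell = {o: base + 3 * i + 2 for i, o in enumerate(self.organs)}
        c = base + 3 * len(self.organs)
        self.cum_dissolved = c
        self.cum_absorbed = c + 1
        self.cum_met = c + 2
        self.cum_renal = c + 3
        self.cum_feces = c + 4
        self.auc_ven = c + 5
        self.auc_cell = {o: c + 6 + i for i, o in enumerate(self.organs)}
        self.n = c + 6 + len(self.organs)

    @property
    def amount_states(self) -> list[int]:
        out = [self.st_solid, self.si_solid, self.st_diss, self.si_diss,
               self.art, self.ven, self.mucosa]
        for o in self.organs:
            out += [self.vas[o], self.ist[o], self.cell[o]]
        return out


# ---------------------------------------------------------------------------
# the model


class PBPKModel:
    """Assembled linear ODE system for one drug / individual / formulation."""

    def __init__(self, drug: DrugParameters, individual: ReferenceIndividual,
                 formulation: FormulationParameters | None = None,
                 settings: SolverSettings | None = None):
        self.drug = drug
        self.individual = individual
        self.formulation = formulation or FormulationParameters()
        self.settings = settings or SolverSettings()
        self.idx = _Index(list(individual.organs))
        self._expm_cache: dict[float, np.ndarray] = {}
        self._b_unit_cache: dict[float, np.ndarray] = {}
        self._build()

    # -- assembly ---------------------------------------------------------
    def _build(self) -> None:
        ind, drug, s = self.individual, self.drug, self.settings
        idx = self.idx
        n = idx.n
        M = np.zeros((n, n))
        self.fu_eff = min(1.0, drug.fu * ind.fu_scale)
        self.binding = {o: intracellular_binding(drug, spec)
                        for o, spec in ind.organs.items()}
        p0 = (s.cellular_permeability if s.cellular_permeability is not None
              else cellular_permeability(drug))
        ces1 = ces1_amounts(ind)

        v_art, v_ven = ind.arterial_plasma_volume, ind.venous_plasma_volume
        k_ge = LN2 / ind.gastric_emptying_halflife
        k_tr = 1.0 / ind.small_intestine_transit_time
        cl_abs = drug.p_int * ind.intestinal_surface_area  # L/min

        # GI lumen
        M[idx.st_solid, idx.st_solid] -= k_ge
        M[idx.si_solid, idx.st_solid] += k_ge
        M[idx.si_solid, idx.si_solid] -= k_tr
        M[idx.cum_feces, idx.si_solid] += k_tr
        M[idx.st_diss, idx.st_diss] -= k_ge
        M[idx.si_diss, idx.st_diss] += k_ge
        k_abs = cl_abs / ind.lumen_volume
        M[idx.si_diss, idx.si_diss] -= k_tr + k_abs
        M[idx.cum_feces, idx.si_diss] += k_tr
        M[idx.mucosa, idx.si_diss] += k_abs
        M[idx.cum_absorbed, idx.si_diss] += k_abs

        # mucosal first-pass layer: absorbed drug transits the enterocyte
        # cytosol (gut-wall CES1 metabolism) before the villus capillaries
        si = ind.organs["small_intestine"]
        bf_muc = intracellular_binding(drug, si)
        area_muc = ind.mucosa_surface_area_per_volume * ind.mucosa_volume
        cl_esc = _effective_permeability(
            drug, si.pH_intracellular, p0,
            ind.mucosa_ionic_permeability_factor) * area_muc
        cl_met_muc = drug.cl_spec * ces1[
            "small_intestine"] * ind.mucosa_volume
        den_muc = ind.mucosa_volume * bf_muc
        M[idx.mucosa, idx.mucosa] -= (cl_esc + cl_met_muc) / den_muc
        # villus capillaries drain to the portal vein: escaped drug joins
        # the liver inflow directly (hepatic first pass)
        M[idx.vas["liver"], idx.mucosa] += cl_esc / den_muc
        M[idx.cum_met, idx.mucosa] += cl_met_muc / den_muc

        co = ind.cardiac_output
        portal = set(ind.portal_organs)
        q_liver_out = ind.organs["liver"].blood_flow + sum(
            ind.organs[p].blood_flow for p in portal)

        for name, organ in ind.organs.items():
            v_vas = organ.vascular_volume
            v_is = organ.interstitial_volume
            v_ic = organ.intracellular_volume
            iv, ii, ic = idx.vas[name], idx.ist[name], idx.cell[name]
            q = organ.blood_flow

            # perfusion in/out
            if name == "lung":
                M[iv, idx.ven] += co / v_ven
                M[iv, iv] -= co / v_vas
                M[idx.art, iv] += co / v_vas
            elif name == "liver":
                M[iv, idx.art] += q / v_art           # hepatic artery
                for p in portal:
                    pv = idx.vas[p]
                    M[iv, pv] += ind.organs[p].blood_flow / ind.organs[p].vascular_volume
                M[iv, iv] -= q_liver_out / v_vas
                M[idx.ven, iv] += q_liver_out / v_vas
            else:
                M[iv, idx.art] += q / v_art
                M[iv, iv] -= q / v_vas
                dest = idx.vas["liver"] if name in portal else idx.ven
                # portal organs drain to the liver vascular space
                if name in portal:
                    pass  # handled from the liver row above (inflow) ...
                else:
                    M[dest, iv] += q / v_vas
            # NOTE: portal organ outflow was added as liver inflow above;
            # its own loss term still needs to be present exactly once.

            # vascular <-> interstitial (fast, perfusion-scaled)
            cl_vi = s.vi_exchange_factor * max(q, 1e-9)
            M[iv, iv] -= cl_vi * self.fu_eff / v_vas
            M[ii, iv] += cl_vi * self.fu_eff / v_vas
            M[ii, ii] -= cl_vi / v_is
            M[iv, ii] += cl_vi / v_is

            # interstitial <-> intracellular, charge-dependent
            sad = organ.cell_surface_area_per_volume
            if sad is None:
                sad = ind.cell_surface_area_per_volume
            area = sad * v_ic
            kap = organ.ionic_permeability_factor
            cl_in = _effective_permeability(drug, organ.pH_interstitial, p0, kap) * area
            cl_out = _effective_permeability(drug, organ.pH_intracellular, p0, kap) * area
            bf = self.binding[name]
            M[ii, ii] -= cl_in / v_is
            M[ic, ii] += cl_in / v_is
            M[ic, ic] -= cl_out / (v_ic * bf)
            M[ii, ic] += cl_out / (v_ic * bf)

            # intracellular CES1 metabolism
            cl_met = drug.cl_spec * ces1[name] * v_ic
            if cl_met > 0:
                M[ic, ic] -= cl_met / (v_ic * bf)
                M[idx.cum_met, ic] += cl_met / (v_ic * bf)

            # AUC integrator for intracellular unbound concentration
            M[idx.auc_cell[name], ic] += 1.0 / (v_ic * bf)

        # arterial outflow: total arterial draw (mass-conserving by rows above)
        q_draw = sum(o.blood_flow for nm, o in ind.organs.items() if nm != "lung")
        M[idx.art, idx.art] -= q_draw / v_art
        M[idx.ven, idx.ven] -= co / v_ven

        # renal elimination from kidney vascular plasma
        kid = ind.organs["kidney"]
        cl_ren = drug.cl_ren * ind.body_weight
        if s.renal_on_unbound:
            cl_ren *= self.fu_eff
        kv = idx.vas["kidney"]
        M[kv, kv] -= cl_ren / kid.vascular_volume
        M[idx.cum_renal, kv] += cl_ren / kid.vascular_volume

        M[idx.auc_ven, idx.ven] += 1.0 / v_ven

        self.M = M
        self._hazard_idx = (idx.st_solid, idx.si_solid, idx.st_diss,
                            idx.si_diss, idx.cum_dissolved)

    # -- volumes / concentrations ----------------------------------------
    def volume_of(self, state: int) -> float:
        """Reference volume (L) turning an amount state into µM."""
        idx, ind = self.idx, self.individual
        if state == idx.art:
            return ind.arterial_plasma_volume
        if state == idx.ven:
            return ind.venous_plasma_volume
        for o, spec in ind.organs.items():
            if state == idx.vas[o]:
                return spec.vascular_volume
            if state == idx.ist[o]:
                return spec.interstitial_volume
            if state == idx.cell[o]:
                return spec.intracellular_volume
        raise KeyError(state)

    # -- integration ------------------------------------------------------
    def _rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.M @ y
        h = _dissolution_hazard(t, self.formulation)
        if h > 0.0:
            i = self._hazard_idx
            ss, sis = y[i[0]], y[i[1]]
            dy[i[0]] -= h * ss
            dy[i[2]] += h * ss
            dy[i[1]] -= h * sis
            dy[i[3]] += h * sis
            dy[i[4]] += h * (ss + sis)
        return dy

    def _jac(self, t: float, y: np.ndarray) -> np.ndarray:
        J = self.M.copy()
        h = _dissolution_hazard(t, self.formulation)
        if h > 0.0:
            i = self._hazard_idx
            J[i[0], i[0]] -= h
            J[i[2], i[0]] += h
            J[i[1], i[1]] -= h
            J[i[3], i[1]] += h
            J[i[4], i[0]] += h
            J[i[4], i[1]] += h
        return J

    def _expm(self, dt: float) -> np.ndarray:
        key = round(dt, 9)
        if key not in self._expm_cache:
            self._expm_cache[key] = expm(self.M * dt)
        return self._expm_cache[key]

    def _solve(self, y0: np.ndarray, span: float,
               t_eval: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Stiff solve over [0, span]; returns (states at t_eval, y(span))."""
        tev = None
        if t_eval is not None and len(t_eval):
            tev = np.unique(np.append(t_eval, span))
        sol = solve_ivp(self._rhs, (0.0, span), y0, method="BDF",
                        jac=self._jac, rtol=self.settings.rtol,
                        atol=self.settings.atol, t_eval=tev)
        if not sol.success:
            raise IntegrationError(f"BDF failed: {sol.message}")
        if t_eval is not None and len(t_eval):
            keep = np.isin(sol.t, t_eval)
            return sol.y[:, keep].T, sol.y[:, -1]
        return np.empty((0, self.idx.n)), sol.y[:, -1]

    def _b_unit(self, span: float) -> np.ndarray:
        """Response at ``span`` to a unit dose in the stomach solid state."""
        key = round(span, 9)
        if key not in self._b_unit_cache:
            y0 = np.zeros(self.idx.n)
            y0[self.idx.st_solid] = 1.0
            _, y_end = self._solve(y0, span, None)
            self._b_unit_cache[key] = y_end
        return self._b_unit_cache[key]

    def _dump_solids(self, y: np.ndarray) -> None:
        idx = self.idx
        y[idx.st_diss] += y[idx.st_solid]
        y[idx.cum_dissolved] += y[idx.st_solid]
        y[idx.st_solid] = 0.0
        y[idx.si_diss] += y[idx.si_solid]
        y[idx.cum_dissolved] += y[idx.si_solid]
        y[idx.si_solid] = 0.0

    def simulate(self, regimen: DoseRegimen,
                 t_out_h: Sequence[float] | None = None,
                 dense_windows_h: Sequence[tuple[float, float]] | None = None,
                 ) -> "SimulationResult":
        """Integrate the model for a dosing regimen.

        ``t_out_h`` are requested output times (hours); ``dense_windows_h``
        adds regularly spaced samples (``dense_resolution_min``) over the
        given windows, e.g. the 24 h after the final dose for Cmax/AUC
        extraction.  Output at a dose time reports the pre-dose (trough)
        state.
        """
        idx = self.idx
        dose_umol = regimen.dose_mg * 1e3 / self.drug.mw
        dose_times = np.asarray(regimen.times_h, float) * 60.0

        t_out = set()
        if t_out_h is not None:
            t_out.update(float(t) * 60.0 for t in t_out_h)
        for (a, b) in (dense_windows_h or ()):
            grid = np.arange(a * 60.0, b * 60.0, self.settings.dense_resolution_min)
            t_out.update(np.append(grid, b * 60.0))
        if not t_out:
            t_out.update(np.arange(0.0, dose_times[-1] + 1441.0, 60.0))
        t_out_arr = np.array(sorted(t_out))
        horizon = max(t_out_arr[-1], dose_times[-1] + 1.0)

        Y = np.zeros((t_out_arr.size, idx.n))
        recorded = np.zeros(t_out_arr.size, bool)
        administered = np.zeros(t_out_arr.size)

        y = np.zeros(idx.n)
        given = 0.0
        # pre-first-dose outputs stay zero
        pre = t_out_arr <= dose_times[0]
        recorded[pre] = True

        fw = self.settings.forcing_window_min
        solution_form = self.formulation.form == "solution"

        for k, tk in enumerate(dose_times):
            t_end = dose_times[k + 1] if k + 1 < dose_times.size else horizon
            span = t_end - tk
            if solution_form:
                y[idx.si_diss] += dose_umol
                y[idx.cum_dissolved] += dose_umol
            given += dose_umol

            sel = (t_out_arr > tk) & (t_out_arr <= t_end) & ~recorded
            t_local = t_out_arr[sel] - tk
            if sel.any() or span <= fw or (not solution_form and y[idx.st_solid] > 0):
                if not solution_form:
                    y[idx.st_solid] += dose_umol
                rows, y = self._solve(y, span, t_local if sel.any() else None)
                if sel.any():
                    Y[sel] = rows
                self._dump_solids(y)
            else:
                y_f = dose_umol * self._b_unit(fw) if not solution_form else 0.0
                y = self._expm(fw) @ y
                if not solution_form:
                    y = y + y_f
                self._dump_solids(y)
                y = self._expm(span - fw) @ y
            recorded[sel] = True
            administered[t_out_arr > tk] = given

        lowest = Y[:, idx.amount_states].min(initial=0.0)
        if lowest < -max(1e-9, 1e-9 * given):
            raise IntegrationError(f"negative state beyond tolerance: {lowest}")
        np.clip(Y, 0.0, None, out=Y)

        return SimulationResult(times_min=t_out_arr, y=Y, model=self,
                                administered_umol=administered,
                                regimen=regimen)

    def steady_state_infusion(self, rate_umol_min: float) -> dict[str, np.ndarray]:
        """Exact steady state under constant venous infusion.

        Solves the linear balance of the distribution states directly
        (no time stepping); requires non-zero elimination.  Returns the
        full state vector (amounts, µmol) under key ``"y"``.
        """
        idx = self.idx
        dyn = [idx.art, idx.ven]
        for o in idx.organs:
            dyn += [idx.vas[o], idx.ist[o], idx.cell[o]]
        sub = self.M[np.ix_(dyn, dyn)]
        u = np.zeros(len(dyn))
        u[dyn.index(idx.ven)] = rate_umol_min
        y_dyn = np.linalg.solve(sub, -u)
        y = np.zeros(idx.n)
        y[dyn] = y_dyn
        return {"y": y}


# ---------------------------------------------------------------------------
# results


ORGAN_QUANTITIES = ("vascular_total", "interstitial_unbound",
                    "intracellular_unbound", "intracellular_total")


@dataclass
class SimulationResult:
    """Time grid plus state matrix with concentration accessors."""

    times_min: np.ndarray
    y: np.ndarray
    model: PBPKModel
    administered_umol: np.ndarray
    regimen: DoseRegimen

    @property
    def times_h(self) -> np.ndarray:
        return self.times_min / 60.0

    def venous_plasma(self) -> np.ndarray:
        """Total venous plasma concentration, µM."""
        return self.y[:, self.model.idx.ven] / self.model.individual.venous_plasma_volume

    def organ(self, name: str, quantity: str = "intracellular_unbound") -> np.ndarray:
        idx, ind = self.model.idx, self.model.individual
        spec = ind.organs[name]
        if quantity == "vascular_total":
            return self.y[:, idx.vas[name]] / spec.vascular_volume
        if quantity == "interstitial_unbound":
            return self.y[:, idx.ist[name]] / spec.interstitial_volume
        if quantity == "intracellular_unbound":
            return self.y[:, idx.cell[name]] / (
                spec.intracellular_volume * self.model.binding[name])
        if quantity == "intracellular_total":
            return self.y[:, idx.cell[name]] / spec.intracellular_volume
        raise ValueError(f"unknown quantity: {quantity}")

    def cumulative(self, which: str) -> np.ndarray:
        """Cumulative amount (µmol): dissolved/absorbed/metabolized/renal/feces."""
        idx = self.model.idx
        key = {"dissolved": idx.cum_dissolved, "absorbed": idx.cum_absorbed,
               "metabolized": idx.cum_met, "renal": idx.cum_renal,
               "feces": idx.cum_feces}[which]
        return self.y[:, key]

    def lumen_amount(self) -> np.ndarray:
        idx = self.model.idx
        return self.y[:, [idx.st_solid, idx.si_solid,
                          idx.st_diss, idx.si_diss]].sum(axis=1)

    def _integral(self, column: int, t0_min: float, t1_min: float) -> float:
        vals = self.y[:, column]
        return float(np.interp(t1_min, self.times_min, vals)
                     - np.interp(t0_min, self.times_min, vals))

    def auc_plasma(self, window_h: tuple[float, float]) -> float:
        """Venous plasma AUC (µM·min) from the solver-consistent integrator."""
        return self._integral(self.model.idx.auc_ven,
                              window_h[0] * 60.0, window_h[1] * 60.0)

    def auc_intracellular_unbound(self, organ: str,
                                  window_h: tuple[float, float]) -> float:
        return self._integral(self.model.idx.auc_cell[organ],
                              window_h[0] * 60.0, window_h[1] * 60.0)

    def mass_balance_residual(self) -> np.ndarray:
        """Relative residual of administered = in-body + eliminated."""
        idx = self.model.idx
        total = self.y[:, idx.amount_states].sum(axis=1)
        total = total + (self.cumulative("renal") + self.cumulative("metabolized")
                         + self.cumulative("feces"))
        scale = np.where(self.administered_umol > 0, self.administered_umol, 1.0)
        return (self.administered_umol - total) / scale

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table of all concentration series."""
        rows = []
        t = self.times_h
        rows.append(pd.DataFrame({
            "time_h": t, "organ": "venous_plasma", "sub_compartment": "plasma",
            "quantity": "total", "value": self.venous_plasma(), "units": "uM"}))
        for o in self.model.idx.organs:
            for q in ORGAN_QUANTITIES:
                sub, kind = q.split("_", 1)
                rows.append(pd.DataFrame({
                    "time_h": t, "organ": o, "sub_compartment": sub,
                    "quantity": kind, "value": self.organ(o, q), "units": "uM"}))
        return pd.concat(rows, ignore_index=True)


def pk_metrics(result: SimulationResult, compartment: str = "plasma",
               window_h: tuple[float, float] | None = None,
               quantity: str = "intracellular_unbound") -> PKMetrics:
    """Cmax, Tmax and AUC for a compartment over a time window.

    ``compartment`` is ``"plasma"`` (total venous) or an organ name.
    Cmax/Tmax come from the dense samples inside the window; plasma and
    intracellular-unbound AUCs come from the ODE-integrated cumulative
    integrals, other quantities from trapezoidal integration of the dense
    series.
    """
    t_h = result.times_h
    if window_h is None:
        window_h = (float(t_h[0]), float(t_h[-1]))
    t0, t1 = window_h
    if t1 <= t0:
        raise ValueError("empty metrics window")
    mask = (t_h >= t0) & (t_h <= t1)
    if not mask.any():
        raise ValueError("window contains no simulated samples")
    series = (result.venous_plasma() if compartment == "plasma"
              else result.organ(compartment, quantity))
    seg = series[mask]
    ts = t_h[mask]
    imax = int(np.argmax(seg))
    if compartment == "plasma":
        auc = result.auc_plasma(window_h)
    elif quantity == "intracellular_unbound":
        auc = result.auc_intracellular_unbound(compartment, window_h)
    else:
        auc = float(np.trapezoid(seg, ts * 60.0))
    return PKMetrics(cmax=float(seg[imax]), tmax_h=float(ts[imax]),
                     auc=auc, window_h=(t0, t1))


def urinary_unchanged_fraction(result: SimulationResult,
                               window_h: tuple[float, float] | None = None) -> float:
    """Fraction of the administered dose excreted unchanged in urine."""
    renal = result.cumulative("renal")
    total_dose = float(result.administered_umol[-1])
    if window_h is None:
        amount = float(renal[-1])
    else:
        amount = float(np.interp(window_h[1] * 60.0, result.times_min, renal)
                       - np.interp(window_h[0] * 60.0, result.times_min, renal))
    return amount / total_dose


# ---------------------------------------------------------------------------
# configuration loading


def _default_drug_path() -> Path:
    return Path(resources.files("nirapbpk.data").joinpath("drug_niraparib.yaml"))  # type: ignore[arg-type]


def load_drug(path: str | Path | None = None) -> DrugParameters:
    """Load drug parameters (default: packaged niraparib values)."""
    raw = yaml.safe_load(Path(path or _default_drug_path()).read_text())
    return DrugParameters(**raw["drug"])


def load_formulation(path: str | Path | None = None) -> FormulationParameters:
    """Load formulation parameters (default: packaged niraparib capsule)."""
    raw = yaml.safe_load(Path(path or _default_drug_path()).read_text())
    return FormulationParameters(**raw["formulation"])
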
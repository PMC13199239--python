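"""Shared fixtures: packaged defaults and a degenerate one-compartment setup."""

from __future__ import annotations

import dataclasses

import pytest

import nirapbpk as npk
from nirapbpk.engine import FormulationParameters, SolverSettings
from nirapbpk.physiology import TissueComposition


@pytest.fixture(scope="session")
def default_individual():
    return npk.load_reference_individual()


@pytest.fixture(scope="session")
def default_drug():
    return npk.load_drug()


@pytest.fixture(scope="session")
def default_formulation():
    return npk.load_formulation()


def make_one_compartment(individual, drug, *, cl_ren=None, cl_spec=0.0,
                         ces1_ref=10.0, flow_scale=1e4):
    """Degenerate configuration behaving as a single well-stirred volume.

    All tissues become pure water at uniform pH with charge-blind, fast
    cellular exchange and unity plasma binding, and perfusion is scaled
    up until mixing is effectively instantaneous.  The exact
    one-compartment oral solution then applies.
    """
    organs = {}
    for name, o in individual.organs.items():
        organs[name] = dataclasses.replace(
            o,
            composition=TissueComposition(1.0, 0.0, 0.0, 0.0),
            pH_interstitial=7.4, pH_intracellular=7.4,
            blood_flow=o.blood_flow * flow_scale,
            ces1_relative_abundance=1.0 if name == "liver" else 0.0,
            cell_surface_area_per_volume=None,
            ionic_permeability_factor=None,
        )
    ind = dataclasses.replace(
        individual, organs=organs,
        cardiac_output=individual.cardiac_output * flow_scale,
        ces1_reference_concentration=ces1_ref,
        cell_surface_area_per_volume=2000.0,
        # mucosal transit made instantaneous and charge-blind
        mucosa_volume=1e-3,
        mucosa_surface_area_per_volume=1e6,
        mucosa_ionic_permeability_factor=1.0,
    )
    ind.validate()
    d = drug.replace(fu=1.0, ionic_permeability_factor=1.0,
                     cl_spec=cl_spec,
                     cl_ren=drug.cl_ren if cl_ren is None else cl_ren)
    form = FormulationParameters(form="solution")
    settings = SolverSettings(cellular_permeability=0.05)
    return d, ind, form, settings


def one_compartment_constants(d, ind):
    """Closed-form constants of the degenerate configuration."""
    v = ind.arterial_plasma_volume + ind.venous_plasma_volume
    for o in ind.organs.values():
        v += o.vascular_volume + o.interstitial_volume + o.intracellular_volume
    ka = d.p_int * ind.intestinal_surface_area / ind.lumen_volume
    k_lum = ka + 1.0 / ind.small_intestine_transit_time
    frac_abs = ka / k_lum
    cl = d.cl_ren * ind.body_weight
    cl_met = d.cl_spec * ind.ces1_reference_concentration * \
        ind.organs["liver"].intracellular_volume
    return {"volume": v, "ka": ka, "k_lum": k_lum, "f_abs": frac_abs,
            "cl_renal": cl, "cl_met": cl_met, "cl_total": cl + cl_met,
            "kel": (cl + cl_met) / v}


@pytest.fixture(scope="session")
def one_compartment(default_individual, default_drug):
    """Renal-only degenerate model plus its analytic constants."""
    d, ind, form, settings = make_one_compartment(
        default_individual, default_drug, cl_ren=2e-3, cl_spec=0.0)
    return d, ind, form, settings, one_compartment_constants(d, ind)
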
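"""Whole-body simulation properties: conservation, linearity, analytic limits."""

import dataclasses

import numpy as np
import pytest

import nirapbpk as npk
from nirapbpk.engine import (
    DoseRegimen,
    PBPKModel,
    SolverSettings,
    pk_metrics,
    urinary_unchanged_fraction,
)

from conftest import make_one_compartment, one_compartment_constants


@pytest.fixture(scope="module")
def qd_result(default_drug, default_individual, default_formulation):
    """28-day 300 mg QD reference simulation with a dense final window."""
    model = PBPKModel(default_drug, default_individual, default_formulation)
    res = model.simulate(DoseRegimen.qd(300.0, 28),
                         t_out_h=[24 * k for k in range(29)],
                         dense_windows_h=[(624.0, 672.0)])
    return res


def test_mass_balance_to_1e6(qd_result):
    residual = qd_result.mass_balance_residual()
    assert np.abs(residual).max() < 1e-6


def test_exact_dose_proportionality(default_drug, default_individual,
                                    default_formulation):
    t_out = [1, 2, 4, 8, 12, 24, 48, 72]
    model = PBPKModel(default_drug, default_individual, default_formulation)
    res_100 = model.simulate(DoseRegimen.qd(100.0, 3), t_out_h=t_out)
    res_300 = model.simulate(DoseRegimen.qd(300.0, 3), t_out_h=t_out)
    ratio = res_300.venous_plasma() / res_100.venous_plasma()
    assert np.allclose(ratio, 3.0, rtol=1e-6)
    for organ in ("bone", "liver", "adipose"):
        ratio = (res_300.organ(organ, "intracellular_unbound")
                 / res_100.organ(organ, "intracellular_unbound"))
        assert np.allclose(ratio, 3.0, rtol=1e-6)


def test_steady_state_reached_by_dose_28(qd_result):
    auc27 = qd_result.auc_plasma((624.0, 648.0))
    auc28 = qd_result.auc_plasma((648.0, 672.0))
    assert abs(auc28 / auc27 - 1.0) < 0.01


def test_interstitial_tracks_plasma_unbound_at_steady_state(
        default_drug, default_individual, default_formulation):
    model = PBPKModel(default_drug, default_individual, default_formulation)
    ss = model.steady_state_infusion(1.0)["y"]
    idx = model.idx
    fu = model.fu_eff
    for organ in ("muscle", "bone", "adipose", "brain"):
        spec = default_individual.organs[organ]
        c_is = ss[idx.ist[organ]] / spec.interstitial_volume
        c_vas_u = fu * ss[idx.vas[organ]] / spec.vascular_volume
        assert c_is == pytest.approx(c_vas_u, rel=0.02)


def test_ion_trap_steady_state_matches_closed_form(default_drug,
                                                   default_individual,
                                                   default_formulation):
    drug = default_drug.replace(ionic_permeability_factor=0.0)
    model = PBPKModel(drug, default_individual, default_formulation)
    ss = model.steady_state_infusion(1.0)["y"]
    idx = model.idx
    expected = (1 + 10 ** (drug.pKa - 7.0)) / (1 + 10 ** (drug.pKa - 7.4))
    for organ in ("muscle", "bone", "gonads", "brain", "adipose"):
        spec = default_individual.organs[organ]
        c_is = ss[idx.ist[organ]] / spec.interstitial_volume
        c_ic = ss[idx.cell[organ]] / (spec.intracellular_volume
                                      * model.binding[organ])
        assert c_ic / c_is == pytest.approx(expected, rel=1e-3)


class TestOneCompartmentOracle:
    """Degenerate configuration vs the analytic oral one-compartment model."""

    def test_plasma_profile_within_0p1_percent(self, one_compartment):
        d, ind, form, settings, k = one_compartment
        model = PBPKModel(d, ind, form, settings)
        t_h = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
        res = model.simulate(DoseRegimen.single(300.0), t_out_h=t_h)
        dose = 300e3 / d.mw
        t = t_h * 60.0
        ka, k_lum, kel, v = k["ka"], k["k_lum"], k["kel"], k["volume"]
        analytic = dose * ka / (v * (k_lum - kel)) * (
            np.exp(-kel * t) - np.exp(-k_lum * t))
        assert np.allclose(res.venous_plasma(), analytic, rtol=1e-3)

    def test_auc_matches_f_dose_over_cl(self, one_compartment):
        d, ind, form, settings, k = one_compartment
        model = PBPKModel(d, ind, form, settings)
        horizon = 12 * 24.0  # ~17 elimination half-lives
        res = model.simulate(DoseRegimen.single(300.0),
                             t_out_h=[0.0, horizon],
                             dense_windows_h=[(0.0, 48.0)])
        dose = 300e3 / d.mw
        expected = k["f_abs"] * dose / k["cl_total"]
        assert res.auc_plasma((0.0, horizon)) == pytest.approx(expected, rel=5e-3)

    def test_urinary_fraction_with_competing_metabolism(self, default_individual,
                                                        default_drug):
        d, ind, form, settings = make_one_compartment(
            default_individual, default_drug, cl_ren=2e-3, cl_spec=5e-3)
        k = one_compartment_constants(d, ind)
        model = PBPKModel(d, ind, form, settings)
        res = model.simulate(DoseRegimen.single(300.0), t_out_h=[0.0, 10 * 24.0])
        expected = k["f_abs"] * k["cl_renal"] / k["cl_total"]
        assert urinary_unchanged_fraction(res) == pytest.approx(expected, rel=5e-3)

    def test_monotone_decay_tmax_at_window_start(self, one_compartment):
        d, ind, form, settings, _ = one_compartment
        model = PBPKModel(d, ind, form, settings)
        res = model.simulate(DoseRegimen.single(300.0),
                             dense_windows_h=[(24.0, 48.0)])
        m = pk_metrics(res, "plasma", (24.0, 48.0))
        assert m.tmax_h == pytest.approx(24.0)


def test_zero_renal_clearance_gives_zero_urine(default_drug, default_individual,
                                               default_formulation):
    drug = default_drug.replace(cl_ren=0.0)
    model = PBPKModel(drug, default_individual, default_formulation)
    res = model.simulate(DoseRegimen.single(300.0), t_out_h=[24.0, 48.0])
    assert urinary_unchanged_fraction(res) == 0.0


def test_metrics_window_validation(qd_result):
    with pytest.raises(ValueError):
        pk_metrics(qd_result, "plasma", (672.0, 648.0))


def test_tidy_export_covers_all_organs(default_drug, default_individual,
                                       default_formulation):
    model = PBPKModel(default_drug, default_individual, default_formulation)
    res = model.simulate(DoseRegimen.single(100.0), t_out_h=[2.0, 6.0])
    df = res.to_frame()
    assert set(df.columns) == {"time_h", "organ", "sub_compartment",
                               "quantity", "value", "units"}
    assert df["organ"].nunique() == 16  # 15 organs + venous plasma
    assert (df["value"] >= 0).all()
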
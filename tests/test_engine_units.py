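"""Closed-form building blocks: ionization, dissolution, partitioning."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirapbpk.engine import (
    FormulationParameters,
    cellular_exchange_rates,
    fraction_neutral,
    intracellular_binding,
    partition_coefficient,
    weibull_dissolved_fraction,
)
from nirapbpk.physiology import OrganSpec, TissueComposition


class TestFractionNeutral:
    @pytest.mark.parametrize("pKa, pH, expected", [
        (9.087, 9.087, 0.5),
        (9.087, 7.4, 0.02014),
        (9.087, 7.0, 0.00812),
    ])
    def test_henderson_hasselbalch_values(self, pKa, pH, expected):
        assert fraction_neutral(pKa, pH) == pytest.approx(expected, rel=1e-3)

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValueError):
            fraction_neutral(9.0, -1.0)

    @given(pKa=st.floats(2.0, 12.0), pH=st.floats(0.0, 14.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, pKa, pH):
        fn = fraction_neutral(pKa, pH)
        assert 0.0 < fn < 1.0
        assert fraction_neutral(pKa, min(pH + 0.5, 14.0)) >= fn


class TestWeibullDissolution:
    form = FormulationParameters(dissolution_time_50pct=30.0, dissolution_shape=2.0)

    def test_zero_at_time_zero(self):
        assert weibull_dissolved_fraction(0.0, self.form) == 0.0

    def test_half_dissolved_at_t50(self):
        assert weibull_dissolved_fraction(30.0, self.form) == pytest.approx(0.5)

    def test_value_at_twice_t50(self):
        # 1 - 2^-4
        assert weibull_dissolved_fraction(60.0, self.form) == pytest.approx(0.9375)

    def test_monotone_nondecreasing(self):
        t = np.linspace(0.0, 240.0, 200)
        f = weibull_dissolved_fraction(t, self.form)
        assert np.all(np.diff(f) >= 0)

    def test_t63_convention(self):
        form63 = FormulationParameters(dissolution_time_50pct=30.0,
                                       dissolution_shape=2.0, convention="t63")
        assert weibull_dissolved_fraction(30.0, form63) == pytest.approx(1 - np.e ** -1)


def _organ(composition, pH_is=7.4, pH_ic=7.0, **kw):
    base = dict(name="test", total_volume=1.0, plasma_fraction=0.05,
                interstitial_fraction=0.15, intracellular_fraction=0.8,
                blood_flow=0.1, composition=composition,
                pH_interstitial=pH_is, pH_intracellular=pH_ic)
    base.update(kw)
    return OrganSpec(**base)


class TestCellularExchange:
    def test_no_gradient_means_unity_ratio(self, default_drug):
        organ = _organ(TissueComposition(0.8, 0.05, 0.01, 0.1),
                       pH_is=7.2, pH_ic=7.2)
        assert cellular_exchange_rates(default_drug, organ).trap_ratio == pytest.approx(1.0)

    def test_ion_trap_ratio_closed_form(self, default_drug):
        # pKa 9.087, 7.4 -> 7.0, no ionic permeability
        drug = default_drug.replace(ionic_permeability_factor=0.0)
        organ = _organ(TissueComposition(0.8, 0.05, 0.01, 0.1))
        assert cellular_exchange_rates(drug, organ).trap_ratio == pytest.approx(2.481, rel=1e-3)

    def test_charge_blind_permeability_kills_trapping(self, default_drug):
        drug = default_drug.replace(ionic_permeability_factor=1.0)
        organ = _organ(TissueComposition(0.8, 0.05, 0.01, 0.1))
        assert cellular_exchange_rates(drug, organ).trap_ratio == pytest.approx(1.0)

    def test_organ_level_ionic_override(self, default_drug):
        drug = default_drug.replace(ionic_permeability_factor=0.0)
        organ = _organ(TissueComposition(0.8, 0.05, 0.01, 0.1),
                       ionic_permeability_factor=1.0)
        assert cellular_exchange_rates(drug, organ).trap_ratio == pytest.approx(1.0)


class TestPartitionCoefficient:
    def test_pure_water_tissue_partitions_as_plasma(self, default_drug):
        # neutral compound (pKa far below pH), unbound in plasma
        drug = default_drug.replace(pKa=1.0, fu=1.0, ionic_permeability_factor=0.0)
        organ = _organ(TissueComposition(1.0, 0.0, 0.0, 0.0), pH_ic=7.4)
        assert partition_coefficient(drug, organ) == pytest.approx(1.0, rel=1e-6)

    def test_monotone_in_lipophilicity(self, default_drug):
        organ = _organ(TissueComposition(0.5, 0.3, 0.05, 0.15))
        ks = [partition_coefficient(default_drug.replace(logP=lp), organ)
              for lp in (1.0, 2.0, 3.0, 4.0)]
        assert all(b >= a for a, b in zip(ks, ks[1:]))

    def test_lipid_rich_tissues_accumulate(self, default_drug, default_individual):
        for organ in ("adipose", "muscle"):
            k = partition_coefficient(default_drug, default_individual.organs[organ])
            assert k > 1.0

    def test_regression_values(self, default_drug, default_individual):
        # frozen outputs of the implemented composition-based scheme
        k_adipose = partition_coefficient(default_drug,
                                          default_individual.organs["adipose"])
        k_muscle = partition_coefficient(default_drug,
                                         default_individual.organs["muscle"])
        assert k_adipose == pytest.approx(3.1762, rel=1e-3)
        assert k_muscle == pytest.approx(3.2643, rel=1e-3)


def test_intracellular_binding_exceeds_water_fraction(default_drug, default_individual):
    for organ in default_individual.organs.values():
        assert intracellular_binding(default_drug, organ) > organ.composition.water
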
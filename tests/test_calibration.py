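"""Discrepancy, mass-balance rejection and ABC-SMC machinery."""

import numpy as np
import pandas as pd
import pytest

import nirapbpk as npk
from nirapbpk.calibration import (
    AbcSmcConfig,
    CalibrationContext,
    CalibrationError,
    MassBalanceConstraint,
    ObservedCohort,
    PriorSpec,
    abc_smc,
    discrepancy,
    mass_balance_accept,
    posterior_credible_band,
    read_cohorts,
    write_cohorts,
)
from nirapbpk.engine import PBPKModel, DoseRegimen

from conftest import make_one_compartment


class TestDiscrepancy:
    def test_zero_for_identical_profiles(self):
        y = [0.3, 1.2, 5.5]
        assert discrepancy(y, y) == 0.0

    def test_mean_squared_log_ratio_values(self):
        # ratios {2, 0.5}: ((ln 2)^2 + (ln 0.5)^2) / 2
        assert discrepancy([2.0, 0.5], [1.0, 1.0]) == pytest.approx(0.4805, abs=1e-4)
        # single ratio e: (ln e)^2 = 1
        assert discrepancy([np.e], [1.0]) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = [1.0, 2.0, 3.0], [1.5, 1.0, 4.0]
        assert discrepancy(a, b) == pytest.approx(discrepancy(b, a))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            discrepancy([1.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            discrepancy([1.0], [1.0, 2.0])


class TestMassBalanceAccept:
    constraint = MassBalanceConstraint(expected_fraction=0.10, halfwidth=0.40)

    def test_exact_match_accepted(self):
        assert mass_balance_accept(0.10, self.constraint)

    def test_relative_window_edges(self):
        assert not mass_balance_accept(0.145, self.constraint)  # > +40%
        assert mass_balance_accept(0.06, self.constraint)       # == -40%
        assert mass_balance_accept(0.14, self.constraint)

    def test_absolute_mode(self):
        c = MassBalanceConstraint(expected_fraction=0.10, halfwidth=0.05,
                                  mode="absolute")
        assert mass_balance_accept(0.145, c)
        assert not mass_balance_accept(0.16, c)


def test_cohort_validation():
    with pytest.raises(ValueError):
        ObservedCohort("s", 100.0, "QD", (1.0, 1.0), (1.0, 2.0))
    with pytest.raises(ValueError):
        ObservedCohort("s", 100.0, "QD", (1.0, 2.0), (1.0, -2.0))
    with pytest.raises(ValueError):
        ObservedCohort("s", 100.0, "weekly", (1.0, 2.0), (1.0, 2.0))


def test_cohort_csv_round_trip(tmp_path):
    cohorts = [
        ObservedCohort("a", 210.0, "QD", (1.0, 4.0, 24.0), (0.5, 1.5, 0.9), n=12),
        ObservedCohort("b", 300.0, "SD", (2.0, 8.0), (1.2, 0.7)),
    ]
    path = tmp_path / "cohorts.csv"
    write_cohorts(cohorts, path)
    back = read_cohorts(path)
    assert len(back) == 2
    assert back[0].times_h == cohorts[0].times_h
    assert back[0].conc_uM == cohorts[0].conc_uM
    assert back[1].n is None


@pytest.fixture(scope="module")
def fast_context(default_individual, default_drug):
    """Cheap one-compartment context for calibration machinery tests."""
    d, ind, form, settings = make_one_compartment(
        default_individual, default_drug, cl_ren=2e-3, cl_spec=5e-3,
        flow_scale=1e3)
    return CalibrationContext(d, ind, form, settings)


@pytest.fixture(scope="module")
def fast_cohort(fast_context):
    model = PBPKModel(fast_context.base_drug, fast_context.individual,
                      fast_context.formulation, fast_context.settings)
    times = (1.0, 2.0, 4.0, 8.0, 24.0)
    res = model.simulate(DoseRegimen.single(300.0), t_out_h=times)
    return ObservedCohort("truth", 300.0, "SD", times,
                          tuple(res.venous_plasma()))


def test_smc_reproducible_and_thresholds_decrease(fast_context, fast_cohort):
    priors = [PriorSpec("cl_ren", 2e-3, 0.5), PriorSpec("p_int", 6.224e-5, 0.5)]
    config = AbcSmcConfig(n_particles=16, n_generations=3, seed=11)
    pops1 = abc_smc([fast_cohort], priors, None, None, config, fast_context)
    pops2 = abc_smc([fast_cohort], priors, None, None, config, fast_context)

    assert [p.epsilon for p in pops1] == [p.epsilon for p in pops2]
    pd.testing.assert_frame_equal(pops1[-1].parameters, pops2[-1].parameters)

    eps = [p.epsilon for p in pops1]
    assert eps[0] == np.inf
    assert eps[2] < eps[1]
    # acceptance definition: every archived particle beats the threshold
    for pop in pops1[1:]:
        assert (pop.rho.max(axis=1) < pop.epsilon).all()


def test_smc_joint_acceptance_across_cohorts(fast_context, fast_cohort):
    inflated = ObservedCohort("inflated", 300.0, "SD", fast_cohort.times_h,
                              tuple(10.0 * c for c in fast_cohort.conc_uM))
    priors = [PriorSpec("cl_ren", 2e-3, 0.5)]
    config = AbcSmcConfig(n_particles=12, n_generations=2, seed=3)
    pops = abc_smc([fast_cohort, inflated], priors, None, None, config,
                   fast_context)
    final = pops[-1]
    assert (final.rho < final.epsilon).all()
    assert final.rho.shape[1] == 2


def test_infeasible_mass_balance_aborts(fast_context, fast_cohort):
    # with renal clearance fixed to zero no parameter can put 90% of the
    # dose in urine
    constraint = MassBalanceConstraint(expected_fraction=0.9, halfwidth=0.4)
    priors = [PriorSpec("p_int", 6.224e-5, 0.5)]
    config = AbcSmcConfig(n_particles=8, n_generations=2, seed=5,
                          min_acceptance_rate=0.05)
    with pytest.raises(CalibrationError, match="acceptance rate"):
        abc_smc([fast_cohort], priors, {"cl_ren": 0.0}, constraint, config,
                fast_context)


def test_posterior_contraction_and_recovery(fast_context, fast_cohort):
    priors = [PriorSpec("cl_ren", 2e-3, 1.0)]
    config = AbcSmcConfig(n_particles=24, n_generations=3, seed=7)
    pops = abc_smc([fast_cohort], priors, None, None, config, fast_context)
    final = pops[-1]
    prior_iqr = priors[0].interquartile_range()
    q = final.parameters["cl_ren"].quantile([0.25, 0.75])
    assert q[0.75] - q[0.25] < prior_iqr
    # noiseless data: posterior median near truth
    assert final.median()["cl_ren"] == pytest.approx(2e-3, rel=0.15)


def test_credible_band_contains_median_and_collapses_for_one_particle(
        fast_context, fast_cohort):
    single = npk.ParticlePopulation(
        generation=0,
        parameters=pd.DataFrame({"cl_ren": [2e-3]}),
        rho=np.zeros((1, 1)), epsilon=np.inf, n_accepted=1, n_attempted=1,
        seed=0)
    band = posterior_credible_band(single, DoseRegimen.single(300.0),
                                   [2.0, 8.0, 24.0], fast_context)
    assert np.allclose(band["lo"], band["median"])
    assert np.allclose(band["hi"], band["median"])

    multi = npk.ParticlePopulation(
        generation=0,
        parameters=pd.DataFrame({"cl_ren": [1.5e-3, 2e-3, 3e-3]}),
        rho=np.zeros((3, 1)), epsilon=np.inf, n_accepted=3, n_attempted=3,
        seed=0)
    band = posterior_credible_band(multi, DoseRegimen.single(300.0),
                                   [2.0, 8.0, 24.0], fast_context)
    assert ((band["lo"] <= band["median"]) & (band["median"] <= band["hi"])).all()
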
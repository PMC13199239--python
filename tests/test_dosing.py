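"""Dose-selection logic on synthetic exposure tables (no simulation)."""

import numpy as np
import pandas as pd
import pytest

from nirapbpk.dosing import (
    DEFAULT_DOSE_GRID,
    ExposureTable,
    adjusted_exposure_report,
    select_dose,
)

#: plasma AUC_ss ratios at 300 mg for the four impaired groups
GROUP_RATIOS = {"NHF": 1.0, "mild": 1.33, "MHI": 1.57,
                "severe60": 1.71, "severe120": 2.01}


def synthetic_table(ratios=GROUP_RATIOS, tissue_spread=1.0):
    """Linear-in-dose exposure table mirroring the simulation output."""
    ref = 4000.0
    rows = []
    for group, r in ratios.items():
        for dose in DEFAULT_DOSE_GRID:
            scale = dose / 300.0
            rows.append(dict(group=group, tbil=0.0, dose_mg=dose,
                             compartment="plasma", metric="auc_ss",
                             value=ref * r * scale))
            rows.append(dict(group=group, tbil=0.0, dose_mg=dose,
                             compartment="plasma", metric="cmax",
                             value=5.0 * r * scale))
            for tissue, tref in (("bone", 1650.0), ("gonads", 1643.0)):
                rows.append(dict(group=group, tbil=0.0, dose_mg=dose,
                                 compartment=tissue, metric="auc_ss",
                                 value=tref * r * scale * tissue_spread))
    df = pd.DataFrame(rows)
    ref_rows = df[(df.group == "NHF") & (df.dose_mg == 300.0)]
    ref_map = ref_rows.set_index(["compartment", "metric"])["value"]
    df["ratio"] = df.apply(
        lambda r: r["value"] / ref_map[(r["compartment"], r["metric"])], axis=1)
    return ExposureTable(df, "NHF", 300.0)


class TestSelectDose:
    def test_plasma_max_rule(self):
        recs = {r.group: r.dose_mg for r in select_dose(synthetic_table())}
        assert recs == {"NHF": 300.0, "mild": 250.0, "MHI": 200.0,
                        "severe60": 200.0, "severe120": 150.0}

    def test_harmonized_severe_rule(self):
        recs = {r.group: r.dose_mg
                for r in select_dose(synthetic_table(), rule="harmonized-severe")}
        # the two severe groups share the lower admissible dose
        assert recs == {"NHF": 300.0, "mild": 250.0, "MHI": 200.0,
                        "severe60": 150.0, "severe120": 150.0}

    def test_zero_tolerance_only_exact_reference(self):
        recs = select_dose(synthetic_table(), tolerance=0.0)
        by_group = {r.group: r for r in recs}
        assert by_group["NHF"].dose_mg == 300.0
        assert not by_group["mild"].admissible
        assert by_group["mild"].dose_mg is None

    def test_invariant_to_common_rescaling(self):
        table = synthetic_table()
        scaled = ExposureTable(table.data.assign(value=table.data.value * 7.3),
                               "NHF", 300.0)
        # ratios are unchanged by a common factor, so selections agree
        ref_map = scaled.data[(scaled.data.group == "NHF")
                              & (scaled.data.dose_mg == 300.0)].set_index(
            ["compartment", "metric"])["value"]
        scaled.data["ratio"] = scaled.data.apply(
            lambda r: r["value"] / ref_map[(r["compartment"], r["metric"])], axis=1)
        assert ([r.dose_mg for r in select_dose(table)]
                == [r.dose_mg for r in select_dose(scaled)])

    def test_recommended_dose_non_increasing_in_severity(self):
        for rule in ("plasma-max", "harmonized-severe"):
            recs = select_dose(synthetic_table(), rule=rule)
            doses = [r.dose_mg for r in recs]  # groups ordered by severity
            assert all(b <= a for a, b in zip(doses, doses[1:]))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            select_dose(synthetic_table(), rule="magic")


class TestAdjustedExposureReport:
    def test_reference_group_ratios_are_one(self):
        table = synthetic_table()
        recs = select_dose(table, rule="harmonized-severe")
        report = adjusted_exposure_report(recs, table)
        nhf = report.tissue_ratios[report.tissue_ratios.group == "NHF"]
        assert np.allclose(nhf["ratio"], 1.0)

    def test_all_ratios_within_tolerance_under_selected_doses(self):
        table = synthetic_table()
        recs = select_dose(table, rule="harmonized-severe")
        report = adjusted_exposure_report(recs, table)
        assert report.tissue_ratios["within_tolerance"].all()
        assert (report.tissue_ratios["ratio"] - 1.0).abs().max() <= 0.20

    def test_bone_to_gonads_ratio_preserved_across_groups(self):
        table = synthetic_table()
        recs = select_dose(table, rule="harmonized-severe")
        report = adjusted_exposure_report(recs, table)
        ratios = report.bone_to_gonads["ratio"]
        assert ratios.max() / ratios.min() - 1.0 < 0.05
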
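import numpy as np
import pandas as pd
import pytest

from pensiongap.simulate import SimulationConfig, generate_records
from pensiongap.tabulate import (
    AGES,
    ExposureDeathTable,
    PeriodDef,
    build_table,
    check_non_overlapping,
    compute_exposure,
    exposure_death_matrices,
    standard_periods,
)

from conftest import as_record_frame, base_record

#: Published person-years and death totals by PI group (first wave 2005-2010
#: and third wave 2015-2018 of the CSWL-based pensioner extract).
WAVE_EXPOSURES_P1 = {"Low": 22_146, "Med-Low": 70_622, "Med-High": 26_169, "High": 28_165}
WAVE_DEATHS_P3 = {"Low": 1_009, "Med-Low": 4_003, "Med-High": 1_040, "High": 1_138}


def table_from_totals(totals: dict[str, dict[str, float]], what: str) -> ExposureDeathTable:
    """One-row-per-group table carrying published totals (age placeholder)."""
    rows = []
    for period, groups in totals.items():
        items = dict(groups)
        items["Total"] = sum(groups.values())
        for level, val in items.items():
            rows.append(
                {
                    "age": 70,
                    "pi_level": level,
                    "period": period,
                    "exposure": val if what == "exposure" else 1.0,
                    "deaths": val if what == "deaths" else 0,
                }
            )
    return ExposureDeathTable(pd.DataFrame(rows))


class TestComputeExposure:
    def test_full_year_split_at_birthday(self):
        # born 1940-03-15, in force all of 2006: 73 days at 65, 292 at 66
        rec = as_record_frame([base_record()])
        out = compute_exposure(rec, PeriodDef.from_years("Y", 2006, 2006))
        assert out == [(65, 73 / 365.25), (66, 292 / 365.25)]

    def test_pension_starting_after_period_is_empty(self):
        rec = as_record_frame([base_record(pension_start_date="2012-01-01")])
        assert compute_exposure(rec, PeriodDef.from_years("Y", 2006, 2006)) == []

    def test_death_on_birthday_attributed_to_age_attained(self):
        rec = as_record_frame(
            [base_record(death_date="2010-03-15", pension_end_date="2010-03-15")]
        )
        E, D = exposure_death_matrices(rec, PeriodDef.from_years("Y", 2010, 2010))
        i70 = int(np.flatnonzero(AGES == 70)[0])
        assert E[0, i70] == 0.0
        assert D[0, i70] == 1

    def test_no_exposure_before_65th_birthday_or_pension_start(self):
        rec = as_record_frame([base_record(pension_start_date="2006-07-01")])
        out = dict(compute_exposure(rec, PeriodDef.from_years("Y", 2006, 2006)))
        assert 65 not in out  # 66th birthday passed before pension start
        assert out[66] == pytest.approx((pd.Timestamp("2007-01-01") - pd.Timestamp("2006-07-01")).days / 365.25)

    def test_old_age_exposure_pooled_at_101(self):
        rec = as_record_frame([base_record(birth_date="1900-06-01", pension_start_date="1965-06-01")])
        out = dict(compute_exposure(rec, PeriodDef.from_years("Y", 2005, 2006)))
        assert set(out) == {101}  # ages 104-106 pooled into the closeout age
        assert out[101] == pytest.approx(730 / 365.25)


class TestBuildTable:
    def test_single_survivor_audit(self):
        rec = as_record_frame([base_record()])
        rec["pi_level"] = "Med-Low"
        table = build_table(rec, [PeriodDef.from_years("Y", 2006, 2006)])
        _, E, D = table.slice("Med-Low", "Y")
        assert D.sum() == 0
        assert E.sum() == pytest.approx(1.0, abs=0.005)  # one calendar year lived

    def test_death_recount_on_simulated_records(self, single_period):
        records = generate_records(SimulationConfig(n_records=1_000, seed=3, contamination_rates={}))
        records["pi_level"] = records["pi_group_true"]
        table = build_table(records, [single_period])
        p0, p1 = pd.Timestamp(single_period.start), pd.Timestamp(single_period.end)
        expected = ((records["death_date"] >= p0) & (records["death_date"] <= p1)).sum()
        got = table.data.query("pi_level != 'Total'")["deaths"].sum()
        assert got == expected

    def test_additivity_over_groups_and_ages(self, single_period):
        records = generate_records(SimulationConfig(n_records=5_000, seed=4, contamination_rates={}))
        records["pi_level"] = records["pi_group_true"]
        table = build_table(records, [single_period])
        by_group = table.data.query("pi_level != 'Total'").groupby("age")[["exposure", "deaths"]].sum()
        total = table.data.query("pi_level == 'Total'").set_index("age")[["exposure", "deaths"]]
        pd.testing.assert_frame_equal(by_group, total, check_like=True)

    def test_overlapping_periods_rejected(self):
        periods = [PeriodDef.from_years("A", 2005, 2010), PeriodDef.from_years("B", 2010, 2014)]
        with pytest.raises(ValueError, match="overlap"):
            check_non_overlapping(periods)
        rec = as_record_frame([base_record()])
        rec["pi_level"] = "Low"
        with pytest.raises(ValueError, match="overlap"):
            build_table(rec, periods)

    def test_crude_rates_match_generating_hazard(self, single_period):
        # crude D/E finite and near the group hazard on a larger simulation
        from pensiongap.simulate import DEFAULT_GROUP_HAZARDS

        records = generate_records(
            SimulationConfig(n_records=60_000, seed=6, contamination_rates={},
                             group_weights=(0.0, 0.0, 0.0, 1.0))
        )
        records["pi_level"] = "High"
        table = build_table(records, [single_period])
        _, E, D = table.slice("High", single_period.label)
        hz = DEFAULT_GROUP_HAZARDS["High"]
        for age in (70, 75, 80):
            i = int(np.flatnonzero(AGES == age)[0])
            assert np.isfinite(D[i] / E[i])
            assert abs(D[i] / E[i] - hz.hazard(age + 0.5)) < 3 * np.sqrt(max(D[i], 1)) / E[i]


class TestShares:
    def test_published_exposure_share_first_wave(self):
        table = table_from_totals({"P1": WAVE_EXPOSURES_P1}, "exposure")
        shares = table.shares().set_index("pi_level")
        assert shares.loc["Low", "pct_exposure"] == 15.05
        assert shares.loc["Total", "exposure"] == 147_102

    def test_published_death_share_third_wave(self):
        table = table_from_totals({"P3": WAVE_DEATHS_P3}, "deaths")
        shares = table.shares().set_index("pi_level")
        assert shares.loc["High", "pct_deaths"] == 15.83
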
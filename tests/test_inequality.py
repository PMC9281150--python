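import numpy as np
import pandas as pd
import pytest

from pensiongap.graduate import GraduatedRateTable, graduate_table, m_to_q
from pensiongap.inequality import (
    AgeGroupScheme,
    RelativeMortalityTable,
    gap_trend,
    improvement_table,
    mortality_improvement,
    percent_excess,
    relative_mortality,
    weighted_bin_rate,
)
from pensiongap.simulate import (
    DEFAULT_GROUP_HAZARDS,
    GompertzMakeham,
    SimulationConfig,
    generate_records,
)
from pensiongap.tabulate import AGES, ExposureDeathTable, PeriodDef, build_table

#: Published all-ages relative mortality ratios by PI group (waves 1 and 3).
RM_TOTAL_P1 = {"Low": 1.18, "Med-Low": 1.13, "Med-High": 0.86, "High": 0.61}
RM_TOTAL_P3 = {"Low": 1.25, "Med-Low": 1.19, "Med-High": 0.78, "High": 0.58}


def rm_table(values: dict[str, dict[str, float]]) -> RelativeMortalityTable:
    df = pd.DataFrame.from_dict(values, orient="index")
    df.index = pd.MultiIndex.from_tuples(
        [(p, "Total") for p in values], names=["period", "age_group"]
    )
    return RelativeMortalityTable.from_rm(df)


class TestRelativeMortality:
    def test_group_rate_equal_to_total_gives_unity(self):
        # RM = 1.00 when the group dies at the rate of its age group as a whole
        q = np.full(37, 0.02)
        E = np.full(37, 100.0)
        scheme = AgeGroupScheme()
        r_group = weighted_bin_rate(AGES, q, E, scheme, "70-74")
        assert r_group / r_group == 1.0

    def test_ratio_arithmetic(self):
        assert 0.03 / 0.02 == pytest.approx(1.5)
        tab = rm_table({"P": {"Low": 1.5, "Med-Low": 1.1, "Med-High": 0.9, "High": 0.8}})
        assert tab.data.loc[("P", "Total"), "dif_low_high"] == pytest.approx(0.7)

    def test_published_low_high_gaps(self):
        tab = rm_table({"P1": RM_TOTAL_P1, "P3": RM_TOTAL_P3})
        pres = tab.presentation()
        assert pres.loc[("P1", "Total"), "dif_low_high"] == 0.57
        assert pres.loc[("P3", "Total"), "dif_low_high"] == 0.67

    def test_weighted_mean_rm_is_one(self, fitted_results):
        res = fitted_results
        rm = relative_mortality(res.graduated, res.exposure_table, total_mode="weighted")
        scheme = AgeGroupScheme()
        for period in res.exposure_table.periods:
            for label in scheme.labels + ["Total"]:
                num = den = 0.0
                for level in res.exposure_table.levels:
                    ages, E, _ = res.exposure_table.slice(level, period)
                    w = E[scheme.mask(ages, label)].sum()
                    num += w * rm.data.loc[(period, label), level]
                    den += w
                assert num / den == pytest.approx(1.0, abs=1e-6)

    def test_rm_invariant_to_common_rate_rescaling(self, fitted_results):
        res = fitted_results
        rm1 = relative_mortality(res.graduated, res.exposure_table)
        scaled = res.graduated.data.copy()
        scaled["q_grad"] *= 3.0
        rm2 = relative_mortality(GraduatedRateTable(scaled), res.exposure_table)
        base_cols = [c for c in rm1.data.columns if c != "dif_low_high"]
        pd.testing.assert_frame_equal(rm1.data[base_cols], rm2.data[base_cols])

    def test_age_bins_partition_full_range(self):
        with pytest.raises(ValueError):
            AgeGroupScheme(bins=(("65-101", 65, 100),))


class TestImprovement:
    def test_identical_rates_give_zero(self):
        q = np.full(5, 0.03)
        assert mortality_improvement(q, q, np.full(5, 10.0)) == 0.0

    def test_halved_rates_give_fifty_percent(self):
        q = np.linspace(0.01, 0.2, 5)
        assert mortality_improvement(q, q / 2, np.full(5, 7.0)) == pytest.approx(50.0)

    def test_zero_earlier_rate_rejected(self):
        with pytest.raises(ValueError):
            mortality_improvement(np.zeros(5), np.full(5, 0.1), np.ones(5))

    def test_engineered_hazard_decline_recovered(self):
        # second period hazard scaled by 0.9 for High only: High improves by
        # about 10%, the other groups by about 0%
        def run(hazards, seed):
            cfg = SimulationConfig(
                n_records=80_000, seed=seed, contamination_rates={},
                group_weights=(0.25, 0.25, 0.25, 0.25), gompertz_params=hazards,
            )
            rec = generate_records(cfg)
            rec["pi_level"] = rec["pi_group_true"]
            return build_table(rec, [PeriodDef.from_years("P", 2005, 2018)])

        base = dict(DEFAULT_GROUP_HAZARDS)
        h = base["High"]
        scaled = dict(base, High=GompertzMakeham(0.9 * h.a, 0.9 * h.b, h.c))
        ta = run(base, seed=31)
        tb = run(scaled, seed=32)
        ra = graduate_table(ta)
        rb = graduate_table(tb)
        for level, expected in [("Low", 0.0), ("Med-Low", 0.0), ("Med-High", 0.0), ("High", 10.0)]:
            _, E, Da = ta.slice(level, "P")
            _, _, Db = tb.slice(level, "P")
            got = mortality_improvement(ra.q(level, "P"), rb.q(level, "P"), E)
            # Poisson-level Monte Carlo tolerance: the relative SE of an
            # exposure-weighted rate is ~1/sqrt(total deaths) per run
            tol = 3 * 100 * np.sqrt(1 / Da.sum() + 1 / Db.sum())
            assert got == pytest.approx(expected, abs=tol), level

    def test_improvement_table_layout(self, fitted_results):
        res = fitted_results
        imp = improvement_table(res.graduated, res.exposure_table)
        pairs = set(imp["period_pair"])
        assert pairs == {"P1-P2", "P2-P3", "P1-P3"}
        assert set(imp["age_group"]) == {"65-69", "70-74", "75-79", "80-84", "85+", "Total"}


class TestGapTrend:
    @staticmethod
    def summary(gaps_by_period: dict[str, float]) -> pd.DataFrame:
        rows = []
        for period, gap in gaps_by_period.items():
            rows.append({"pi_level": "Low", "period": period, "age": 65, "le": 18.0})
            rows.append({"pi_level": "High", "period": period, "age": 65, "le": 18.0 + gap})
        return pd.DataFrame(rows)

    def test_equal_les_give_zero_gap_and_slope(self):
        out = gap_trend(self.summary({"P1": 0.0, "P2": 0.0}))
        assert out["gaps"] == {"P1": 0.0, "P2": 0.0}
        assert out["slope"] == 0.0

    def test_published_two_point_trend(self):
        # gap 1.49 years widening to 2.58: slope 1.09 per period step
        out = gap_trend(self.summary({"P1": 1.49, "P3": 2.58}))
        assert out["slope"] == pytest.approx(1.09)

    def test_exact_ols_on_collinear_points(self):
        out = gap_trend(self.summary({"P1": 1.0, "P2": 2.0, "P3": 3.0}))
        assert out["slope"] == pytest.approx(1.0)

    def test_single_period_rejected(self):
        with pytest.raises(ValueError):
            gap_trend(self.summary({"P1": 1.0}))


def test_percent_excess_of_regime_benefits():
    # mean annual benefit EUR 17,291 (general regime) vs EUR 10,196
    # (self-employed): the general regime pays 70% more (rounded)
    assert percent_excess(17_291, 10_196) == 70
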
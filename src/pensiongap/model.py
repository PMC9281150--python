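"""Model/Results facade over the full mortality-gradient pipeline.

:class:`MortalityGradientModel` holds the raw records plus the analysis
design (periods, PI thresholds, graduation settings); :meth:`fit` runs the
exclusion cascade, PI classification, exposure/death tabulation, P-spline
graduation, life tables and inequality statistics, and returns a
:class:`GradientResults` carrying the estimates, their uncertainties and a
``summary()`` table, in the style of statsmodels results objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    FilterReport,
    PIThresholds,
    ThresholdTable,
    apply_exclusions,
    assign_pi_levels,
)
from .graduate import GraduatedRateTable, GraduationSettings, graduate_table
from .inequality import (
    AgeGroupScheme,
    RelativeMortalityTable,
    gap_trend,
    improvement_table,
    relative_mortality,
)
from .lifetable import (
    LEDifference,
    LEEstimate,
    LifeTable,
    build_life_table,
    chiang_variance,
    test_le_difference,
)
from .simulate import PI_LEVELS, SimulationConfig, generate_records
from .tabulate import ExposureDeathTable, PeriodDef, build_table, standard_periods

TOTAL = "Total"
LE_AGES = (65, 75)


class MortalityGradientModel:
    """Mortality gradient by pension-income level, from pensioner records.

    Parameters
    ----------
    records : DataFrame
        Raw registry records (schema of :data:`pensiongap.simulate.RECORD_COLUMNS`).
    thresholds : PIThresholds | ThresholdTable
        Legal minimum/maximum benefits defining the PI groups.
    periods : list[PeriodDef], optional
        Study periods; defaults to the three standard periods 2005-2010,
        2011-2014, 2015-2018.
    settings : GraduationSettings, optional
    """

    def __init__(
        self,
        records: pd.DataFrame,
        thresholds: PIThresholds | ThresholdTable,
        periods: list[PeriodDef] | None = None,
        settings: GraduationSettings | None = None,
    ):
        self.records = records
        self.thresholds = thresholds
        self.periods = periods or standard_periods()
        self.settings = settings or GraduationSettings()

    @classmethod
    def from_csv(cls, path, thresholds, periods=None, settings=None) -> "MortalityGradientModel":
        from .io import read_records

        return cls(read_records(path), thresholds, periods, settings)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, periods=None, settings=None
    ) -> "MortalityGradientModel":
        records = generate_records(config)
        thresholds = PIThresholds(config.min_benefit, config.max_benefit)
        return cls(records, thresholds, periods, settings)

    @property
    def reference_period(self) -> tuple:
        start = min(p.start for p in self.periods)
        end = max(p.end for p in self.periods)
        return (start, end)

    def fit(self, graduation_method: str = "pspline", bandwidth: float | None = None) -> "GradientResults":
        """Run the full pipeline and return a results object."""
        cohort, report = apply_exclusions(self.records, self.reference_period)
        cohort = assign_pi_levels(cohort, self.thresholds)
        exposure = build_table(cohort, self.periods)
        graduated = graduate_table(
            exposure, self.settings, method=graduation_method, bandwidth=bandwidth
        )

        life_tables: dict[tuple[str, str], LifeTable] = {}
        estimates: dict[tuple[str, str, int], LEEstimate] = {}
        rows = []
        for period in exposure.periods:
            for level in exposure.levels + [TOTAL]:
                ages, E, _ = exposure.slice(level, period)
                m = graduated.m(level, period)
                q = graduated.q(level, period)
                lt = build_life_table(q, m_closeout=float(m[-1]))
                life_tables[(level, period)] = lt
                eff_deaths = E * m
                for age in LE_AGES:
                    var = chiang_variance(lt.q, eff_deaths, lt, start_age=age)
                    est = LEEstimate(level, period, age, lt.expectancy(age), var)
                    estimates[(level, period, age)] = est
                    rows.append(
                        {
                            "pi_level": level,
                            "period": period,
                            "age": age,
                            "le": est.le,
                            "var": est.var,
                            "ci_lo": est.ci_lo,
                            "ci_hi": est.ci_hi,
                        }
                    )
        le_summary = pd.DataFrame(rows)

        rm = relative_mortality(graduated, exposure)
        improvements = None
        trends = {}
        if len(exposure.periods) >= 2:
            improvements = improvement_table(graduated, exposure)
            group_summary = le_summary[le_summary["pi_level"] != TOTAL]
            for age in LE_AGES:
                trends[age] = gap_trend(group_summary, age=age)

        differences = []
        levels = [lv for lv in exposure.levels if lv != TOTAL]
        order = {lv: i for i, lv in enumerate(PI_LEVELS)}
        for period in exposure.periods:
            for age in LE_AGES:
                for i, rich in enumerate(levels):
                    for poor in levels[:i]:
                        if order.get(rich, i) <= order.get(poor, 0):
                            continue
                        differences.append(
                            test_le_difference(
                                estimates[(rich, period, age)],
                                estimates[(poor, period, age)],
                            )
                        )

        return GradientResults(
            model=self,
            cohort=cohort,
            filter_report=report,
            exposure_table=exposure,
            graduated=graduated,
            life_tables=life_tables,
            le_estimates=estimates,
            le_summary=le_summary,
            rm_table=rm,
            improvements=improvements,
            gap_trends=trends,
            le_differences=differences,
        )


@dataclass
class GradientResults:
    """Fitted pipeline: estimates, uncertainties, diagnostics, summaries."""

    model: MortalityGradientModel
    cohort: pd.DataFrame
    filter_report: FilterReport
    exposure_table: ExposureDeathTable
    graduated: GraduatedRateTable
    life_tables: dict
    le_estimates: dict
    le_summary: pd.DataFrame
    rm_table: RelativeMortalityTable
    improvements: pd.DataFrame | None
    gap_trends: dict
    le_differences: list = field(default_factory=list)

    def le(self, pi_level: str, period: str, age: int = 65) -> LEEstimate:
        return self.le_estimates[(pi_level, period, age)]

    def differences_frame(self) -> pd.DataFrame:
        rows = [
            {
                "period": d.period,
                "age": d.age,
                "group_a": d.group_a,
                "group_b": d.group_b,
                "dle": d.dle,
                "se": d.se,
                "z": d.z,
                "significance": d.significance,
            }
            for d in self.le_differences
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable overview of the fitted gradient."""
        lines = ["Mortality gradient by pension-income level", "=" * 44]
        lines.append(str(self.filter_report))
        lines.append("")
        lines.append("Life expectancy (years) with 95% CI")
        for age in LE_AGES:
            lines.append(f"  LE_{age}")
            sub = self.le_summary[self.le_summary["age"] == age]
            for _, r in sub.iterrows():
                lines.append(
                    f"    {r['period']:<4} {r['pi_level']:<9} "
                    f"{r['le']:6.2f}  [{r['ci_lo']:6.2f}, {r['ci_hi']:6.2f}]"
                )
        lines.append("")
        lines.append("Relative mortality (all ages), Dif Low-High")
        pres = self.rm_table.presentation()
        for period in self.exposure_table.periods:
            row = pres.loc[(period, TOTAL)]
            line = f"  {period}: " + "  ".join(
                f"{lv} {row[lv]:.2f}" for lv in self.exposure_table.levels
            )
            if "dif_low_high" in row:
                line += f"  dif {row['dif_low_high']:.2f}"
            lines.append(line)
        if self.gap_trends:
            lines.append("")
            for age, tr in self.gap_trends.items():
                gaps = ", ".join(f"{p}: {g:.2f}" for p, g in tr["gaps"].items())
                lines.append(
                    f"LE_{age} High-Low gap (years): {gaps}; trend slope "
                    f"{tr['slope']:+.2f}/period"
                )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        out = {
            "filter": {
                "initial": self.filter_report.initial_count,
                "final": self.filter_report.final_count,
                "retention_pct": self.filter_report.retention_pct,
                "exclusions": dict(self.filter_report.exclusions),
            },
            "le": self.le_summary.to_dict(orient="records"),
            "rm_total": {
                period: {
                    lv: float(self.rm_table.data.loc[(period, TOTAL), lv])
                    for lv in self.exposure_table.levels
                }
                for period in self.exposure_table.periods
            },
            "gap_trends": {
                str(age): {"gaps": tr["gaps"], "slope": tr["slope"]}
                for age, tr in self.gap_trends.items()
            },
            "differences": self.differences_frame().to_dict(orient="records"),
        }
        return out

    def plot_le(self, age: int = 65, ax=None):
        """LE by period, one line per PI group (with 95% CI bars)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        sub = self.le_summary[self.le_summary["age"] == age]
        periods = self.exposure_table.periods
        x = np.arange(len(periods))
        for level in self.exposure_table.levels + [TOTAL]:
            s = sub[sub["pi_level"] == level].set_index("period").reindex(periods)
            style = dict(marker="o")
            if level == TOTAL:
                style.update(color="black", linestyle="--")
            ax.errorbar(
                x, s["le"], yerr=[s["le"] - s["ci_lo"], s["ci_hi"] - s["le"]],
                label=level, capsize=3, **style,
            )
        ax.set_xticks(x, periods)
        ax.set_ylabel(f"LE at {age} (years)")
        ax.set_xlabel("period")
        ax.legend(title="PI level", fontsize=8)
        return ax

    def save(self, outdir: str | Path, figures: bool = True) -> list[str]:
        """Write every stage output under ``outdir``; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: list[str] = []

        def write(name: str, fn) -> None:
            fn(outdir / name)
            manifest.append(name)

        from .io import write_records

        write("cohort.csv", lambda p: write_records(self.cohort, p))
        write("filter_report.csv", lambda p: self.filter_report.to_frame().to_csv(p, index=False, lineterminator="\n"))
        write("filter_report.txt", lambda p: p.write_text(str(self.filter_report) + "\n"))
        write("exposure_deaths.csv", lambda p: self.exposure_table.to_csv(p))
        write("graduated_rates.csv", lambda p: self.graduated.to_csv(p))
        for (level, period), lt in self.life_tables.items():
            safe = level.lower().replace("-", "_")
            write(
                f"life_table_{safe}_{period.lower()}.csv",
                lambda p, lt=lt: lt.to_frame().to_csv(p, index=False, lineterminator="\n"),
            )
        write("le_summary.csv", lambda p: self.le_summary.to_csv(p, index=False, lineterminator="\n"))
        write(
            "relative_mortality.csv",
            lambda p: self.rm_table.presentation().to_csv(p, lineterminator="\n"),
        )
        if self.improvements is not None:
            write("improvements.csv", lambda p: self.improvements.to_csv(p, index=False, lineterminator="\n"))
        write("le_differences.csv", lambda p: self.differences_frame().to_csv(p, index=False, lineterminator="\n"))
        write(
            "summary.json",
            lambda p: p.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n"),
        )
        write("summary.txt", lambda p: p.write_text(self.summary() + "\n"))
        if figures:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for age in LE_AGES:
                ax = self.plot_le(age=age)
                fig = ax.figure
                fig.tight_layout()
                name = f"le{age}_by_group.png"
                fig.savefig(outdir / name, dpi=120)
                plt.close(fig)
                manifest.append(name)
        (outdir / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
        return manifest
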
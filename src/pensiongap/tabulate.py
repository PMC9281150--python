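"""Person-years exposure and death counts by age, PI group and period.

Exposure accrues on the age-last-birthday basis: each record contributes the
days lived at each completed age x in [65, 101] inside the study period,
between max(pension start, period start, 65th birthday) and min(death,
pension end, period end), split at exact calendar birthdays and divided by
365.25.  Ages above 101 are pooled into 101 (the life-table closeout age).
A death on an exact birthday is attributed to the age just attained,
consistent with half-open [birthday, next-birthday) age intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .simulate import PI_LEVELS

AGE_MIN = 65
AGE_MAX = 101
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
DAYS_PER_YEAR = 365.25
TOTAL = "Total"


@dataclass(frozen=True)
class PeriodDef:
    """One study period, calendar dates, end inclusive."""

    label: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if pd.Timestamp(self.start) > pd.Timestamp(self.end):
            raise ValueError(f"period {self.label}: start {self.start} after end {self.end}")

    @classmethod
    def from_years(cls, label: str, start_year: int, end_year: int) -> "PeriodDef":
        return cls(label, date(start_year, 1, 1), date(end_year, 12, 31))


def standard_periods() -> list[PeriodDef]:
    """The three study periods: 2005-2010, 2011-2014, 2015-2018."""
    return [
        PeriodDef.from_years("P1", 2005, 2010),
        PeriodDef.from_years("P2", 2011, 2014),
        PeriodDef.from_years("P3", 2015, 2018),
    ]


def check_non_overlapping(periods: list[PeriodDef]) -> None:
    ordered = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if pd.Timestamp(b.start) <= pd.Timestamp(a.end):
            raise ValueError(f"periods {a.label} and {b.label} overlap")


def _birthday(birth: pd.Series, years: int) -> pd.Series:
    """Exact calendar birthday ``years`` after birth; Feb 29 falls to Mar 1."""
    parts = pd.DataFrame(
        {"year": birth.dt.year + years, "month": birth.dt.month, "day": birth.dt.day}
    )
    out = pd.to_datetime(parts, errors="coerce")
    bad = out.isna() & birth.notna()
    if bad.any():
        fallback = pd.to_datetime(
            {"year": parts.loc[bad, "year"], "month": 3, "day": 1}
        )
        out.loc[bad] = fallback
    return out


def exposure_death_matrices(
    cohort: pd.DataFrame, period: PeriodDef
) -> tuple[np.ndarray, np.ndarray]:
    """Per-record exposure (person-years) and death indicator matrices.

    Returns ``(E, D)`` of shape ``(len(cohort), len(AGES))``; summing rows
    reproduces the aggregate table, which makes record-level bootstrap
    resampling cheap.
    """
    n = len(cohort)
    E = np.zeros((n, len(AGES)))
    D = np.zeros((n, len(AGES)), dtype=np.int64)
    if n == 0:
        return E, D

    birth = pd.to_datetime(cohort["birth_date"])
    pstart = pd.to_datetime(cohort["pension_start_date"])
    pend = pd.to_datetime(cohort["pension_end_date"])
    death = pd.to_datetime(cohort["death_date"])

    p0 = pd.Timestamp(period.start)
    p1x = pd.Timestamp(period.end) + pd.Timedelta(days=1)  # exclusive
    base = pstart.clip(lower=p0)
    stop = pd.Series(p1x, index=cohort.index)
    stop = stop.where(pend.isna(), np.minimum(stop, pend + pd.Timedelta(days=1)))
    stop = stop.where(death.isna(), np.minimum(stop, death))

    bdays = {x: _birthday(birth, x) for x in range(AGE_MIN, AGE_MAX + 2)}
    for i, x in enumerate(AGES):
        lo = np.maximum(base, bdays[x])
        hi = stop if x == AGE_MAX else np.minimum(stop, bdays[x + 1])
        days = (hi - lo).dt.days.clip(lower=0).fillna(0).to_numpy()
        E[:, i] = days / DAYS_PER_YEAR

    died = death.notna() & (death >= p0) & (death < p1x)
    if died.any():
        age_at_death = np.zeros(n, dtype=int)
        for x in range(AGE_MIN, AGE_MAX + 2):
            age_at_death += (death >= bdays[x]).to_numpy(dtype=int)
        age_at_death = np.clip(age_at_death + AGE_MIN - 1, AGE_MIN, AGE_MAX)
        idx = np.flatnonzero(died.to_numpy())
        D[idx, age_at_death[idx] - AGE_MIN] = 1
    return E, D


def compute_exposure(record, period: PeriodDef) -> list[tuple[int, float]]:
    """Exposure of one record: list of (age, person-years), positive entries only."""
    df = pd.DataFrame([record]) if not isinstance(record, pd.DataFrame) else record
    E, _ = exposure_death_matrices(df, period)
    return [(int(x), float(e)) for x, e in zip(AGES, E[0]) if e > 0]


class ExposureDeathTable:
    """Long-format exposures/deaths keyed by (age, pi_level, period).

    Includes a ``Total`` pseudo-group (sum over PI groups).  ``data`` has
    columns ``age, pi_level, period, exposure, deaths``.
    """

    def __init__(self, data: pd.DataFrame, levels=PI_LEVELS):
        self.data = data.reset_index(drop=True)
        self.levels = list(levels)

    @property
    def periods(self) -> list[str]:
        return list(dict.fromkeys(self.data["period"]))

    def slice(self, pi_level: str, period: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ages, exposure, deaths) arrays for one group and period."""
        sub = self.data[(self.data["pi_level"] == pi_level) & (self.data["period"] == period)]
        sub = sub.set_index("age").reindex(AGES)
        return AGES.copy(), sub["exposure"].fillna(0).to_numpy(), sub["deaths"].fillna(0).to_numpy()

    def totals(self) -> pd.DataFrame:
        """Exposure and death totals per (pi_level, period)."""
        return (
            self.data.groupby(["period", "pi_level"], sort=False)[["exposure", "deaths"]]
            .sum()
            .reset_index()
        )

    def shares(self) -> pd.DataFrame:
        """Percent shares of exposure and deaths by PI group within period.

        Shares are relative to the ``Total`` pseudo-group, rounded to 2
        decimals as presented.
        """
        tot = self.totals()
        out = []
        for period in self.periods:
            sub = tot[tot["period"] == period].set_index("pi_level")
            e_tot = sub.loc[TOTAL, "exposure"]
            d_tot = sub.loc[TOTAL, "deaths"]
            for level in self.levels + [TOTAL]:
                out.append(
                    {
                        "period": period,
                        "pi_level": level,
                        "exposure": sub.loc[level, "exposure"],
                        "pct_exposure": round(100.0 * sub.loc[level, "exposure"] / e_tot, 2)
                        if e_tot > 0
                        else float("nan"),
                        "deaths": sub.loc[level, "deaths"],
                        "pct_deaths": round(100.0 * sub.loc[level, "deaths"] / d_tot, 2)
                        if d_tot > 0
                        else float("nan"),
                    }
                )
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "ExposureDeathTable":
        return cls(pd.read_csv(path))


def build_table(cohort: pd.DataFrame, periods: list[PeriodDef]) -> ExposureDeathTable:
    """Tabulate a classified cohort (needs ``pi_level``) into an ExposureDeathTable."""
    check_non_overlapping(periods)
    if "pi_level" not in cohort.columns:
        raise ValueError("cohort must carry a pi_level column (see assign_pi_levels)")
    rows = []
    levels = [lv for lv in PI_LEVELS if lv in set(cohort["pi_level"])] or list(PI_LEVELS)
    for period in periods:
        E, D = exposure_death_matrices(cohort, period)
        group_e = {}
        group_d = {}
        for level in levels:
            mask = (cohort["pi_level"] == level).to_numpy()
            group_e[level] = E[mask].sum(axis=0)
            group_d[level] = D[mask].sum(axis=0)
        group_e[TOTAL] = sum(group_e[lv] for lv in levels)
        group_d[TOTAL] = sum(group_d[lv] for lv in levels)
        for level in levels + [TOTAL]:
            for i, x in enumerate(AGES):
                rows.append(
                    {
                        "age": int(x),
                        "pi_level": level,
                        "period": period.label,
                        "exposure": float(group_e[level][i]),
                        "deaths": int(group_d[level][i]),
                    }
                )
    return ExposureDeathTable(pd.DataFrame(rows), levels=levels)
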
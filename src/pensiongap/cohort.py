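"""Exclusion cascade and pension-income classification.

The analysis population is male general-regime retirement pensioners who
entered at the statutory age (65) or later.  Raw registry records are sifted
through a fixed cascade of exclusion rules — technical defects (invalid birth
dates, administrative errors, benefits still recorded for pensioners already
dead at the start of the reference period) and group-selection rules (female
records, non-retirement benefits, early retirees, special schemes).  A record
failing several rules is counted once, under the first failing rule, so the
resulting report conserves counts.

Surviving records are classified into four pension-income (PI) groups from
the initial monthly benefit B relative to the legal minimum (Min) and maximum
(Max) benefits in force in the year of retirement:

    Low       : B <= Min
    Med-Low   : Min < B <= 0.5*Max + 0.33*Min
    Med-High  : 0.5*Max + 0.33*Min < B <= 0.75*Max
    High      : B > 0.75*Max

The 0.33 coefficient is used literally (not 1/3).  Groups are fixed at
retirement and never reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PI_LEVELS

#: Fixed precedence order of the exclusion cascade.
EXCLUSION_ORDER = (
    "invalid_birth_date",
    "female",
    "non_retirement",
    "administrative_error",
    "deceased_benefit",
    "early_retirement",
    "special_scheme",
    "other_technical",
)


@dataclass(frozen=True)
class PIThresholds:
    """Legal minimum and maximum monthly benefits for one retirement year."""

    min_benefit: float
    max_benefit: float
    year: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_benefit < self.max_benefit:
            raise ValueError(
                f"need 0 < Min < Max, got Min={self.min_benefit}, Max={self.max_benefit}"
            )

    @property
    def cut_low(self) -> float:
        return self.min_benefit

    @property
    def cut_med(self) -> float:
        return 0.5 * self.max_benefit + 0.33 * self.min_benefit

    @property
    def cut_high(self) -> float:
        return 0.75 * self.max_benefit


@dataclass
class ThresholdTable:
    """Year -> PIThresholds lookup ("in force at the time of retirement").

    A year without an entry falls back to the nearest listed year (ties to
    the earlier one).
    """

    by_year: dict[int, PIThresholds] = field(default_factory=dict)

    @classmethod
    def constant(cls, thresholds: PIThresholds) -> "ThresholdTable":
        return cls({thresholds.year if thresholds.year is not None else 0: thresholds})

    @classmethod
    def from_config(cls, cfg: dict) -> "ThresholdTable":
        """Build from ``{year: {min_eur: ..., max_eur: ...}}``."""
        table = {
            int(y): PIThresholds(float(v["min_eur"]), float(v["max_eur"]), int(y))
            for y, v in cfg.items()
        }
        return cls(table)

    def for_year(self, year: int) -> PIThresholds:
        if not self.by_year:
            raise ValueError("empty threshold table")
        if year in self.by_year:
            return self.by_year[year]
        best = min(self.by_year, key=lambda y: (abs(y - year), y))
        return self.by_year[best]


def classify_pi(benefit: float, thresholds: PIThresholds) -> str:
    """Classify one monthly benefit into its PI group (Low .. High)."""
    if benefit < 0 or not np.isfinite(benefit):
        raise ValueError(f"benefit must be a nonnegative number, got {benefit}")
    if benefit <= thresholds.cut_low:
        return "Low"
    if benefit <= thresholds.cut_med:
        return "Med-Low"
    if benefit <= thresholds.cut_high:
        return "Med-High"
    return "High"


def classify_pi_array(benefits: np.ndarray, thresholds: PIThresholds) -> np.ndarray:
    b = np.asarray(benefits, dtype=float)
    if (b < 0).any() or not np.isfinite(b).all():
        raise ValueError("benefits must be nonnegative finite numbers")
    out = np.select(
        [b <= thresholds.cut_low, b <= thresholds.cut_med, b <= thresholds.cut_high],
        ["Low", "Med-Low", "Med-High"],
        default="High",
    )
    return out.astype(object)


@dataclass
class FilterReport:
    """Auditable record of the exclusion cascade.

    ``initial_count = final_count + sum(exclusions)`` always holds;
    percentages are recomputed from counts.
    """

    initial_count: int
    exclusions: dict[str, int]
    final_count: int

    def __post_init__(self) -> None:
        for key in self.exclusions:
            if key not in EXCLUSION_ORDER:
                raise ValueError(f"unknown exclusion category {key!r}")
        self.exclusions = {k: int(self.exclusions.get(k, 0)) for k in EXCLUSION_ORDER}
        total = self.final_count + sum(self.exclusions.values())
        if total != self.initial_count:
            raise ValueError(
                f"count conservation violated: initial {self.initial_count}, "
                f"final + exclusions {total}"
            )

    @classmethod
    def from_counts(cls, initial_count: int, exclusions: dict[str, int]) -> "FilterReport":
        final = initial_count - sum(exclusions.values())
        return cls(initial_count, dict(exclusions), final)

    def percentage(self, count: int) -> float:
        if self.initial_count == 0:
            return 0.0
        return round(100.0 * count / self.initial_count, 2)

    @property
    def retention_pct(self) -> float:
        return self.percentage(self.final_count)

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", self.initial_count, self.percentage(self.initial_count))]
        rows += [
            (name, -cnt, -self.percentage(cnt)) for name, cnt in self.exclusions.items()
        ]
        rows.append(("final", self.final_count, self.retention_pct))
        return pd.DataFrame(rows, columns=["item", "count", "pct_of_initial"])

    def __str__(self) -> str:
        lines = ["Exclusion cascade"]
        for _, row in self.to_frame().iterrows():
            lines.append(f"  {row['item']:<22} {row['count']:>12,d} {row['pct_of_initial']:>8.2f}%")
        return "\n".join(lines)


def _as_dates(reference_period) -> tuple[pd.Timestamp, pd.Timestamp]:
    if hasattr(reference_period, "start") and hasattr(reference_period, "end"):
        start, end = reference_period.start, reference_period.end
    else:
        start, end = reference_period
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError(f"reference period start {start.date()} after end {end.date()}")
    return start, end


def apply_exclusions(
    records: pd.DataFrame, reference_period
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion cascade; return (cohort, FilterReport).

    ``reference_period`` is anything with ``start``/``end`` attributes or a
    ``(start, end)`` pair of dates; it defines "deceased before the study"
    and "entered after the study" exclusions.  Records with unparseable or
    inconsistent fields are counted (never silently dropped): missing or
    impossible birth dates first, other field defects under
    ``administrative_error``.
    """
    start, end = _as_dates(reference_period)
    df = records
    n = len(df)
    if n == 0:
        return df.copy(), FilterReport.from_counts(0, {})

    birth = pd.to_datetime(df["birth_date"], errors="coerce")
    pstart = pd.to_datetime(df["pension_start_date"], errors="coerce")
    pend = pd.to_datetime(df["pension_end_date"], errors="coerce")
    death = pd.to_datetime(df["death_date"], errors="coerce")
    ret_age = pd.to_numeric(df["retirement_age_years"], errors="coerce")
    pension = pd.to_numeric(df["initial_pension_eur_month"], errors="coerce")

    invalid_birth = birth.isna() | (pstart.notna() & (birth >= pstart))
    admin = (
        pstart.isna()
        | (pend.notna() & pstart.notna() & (pend < pstart))
        | (death.notna() & pstart.notna() & (death < pstart))
        | ret_age.isna()
        | pension.isna()
        | (pension < 0)
    )
    conditions = [
        invalid_birth,
        (df["sex"] != "male").to_numpy(),
        df["benefit_type"].isin(["disability", "survivor", "other"]).to_numpy(),
        admin.to_numpy(),
        (death.notna() & (death < start)).to_numpy(),
        ((df["benefit_type"] == "early_retirement") | (ret_age < 65)).to_numpy(),
        (df["regime"] != "general").to_numpy(),
        (pstart > end).to_numpy(),
    ]
    reason = np.select(conditions, list(EXCLUSION_ORDER), default="")

    counts = {cat: int((reason == cat).sum()) for cat in EXCLUSION_ORDER}
    cohort = df.loc[reason == ""].copy()
    report = FilterReport.from_counts(n, counts)
    assert report.final_count == len(cohort)
    return cohort, report


def assign_pi_levels(
    cohort: pd.DataFrame, thresholds: PIThresholds | ThresholdTable
) -> pd.DataFrame:
    """Attach a ``pi_level`` column using the thresholds of the retirement year."""
    out = cohort.copy()
    benefits = pd.to_numeric(out["initial_pension_eur_month"]).to_numpy(dtype=float)
    if isinstance(thresholds, PIThresholds):
        out["pi_level"] = classify_pi_array(benefits, thresholds)
        return out
    years = pd.to_datetime(out["pension_start_date"]).dt.year.to_numpy()
    levels = np.empty(len(out), dtype=object)
    for year in np.unique(years):
        mask = years == year
        levels[mask] = classify_pi_array(benefits[mask], thresholds.for_year(int(year)))
    out["pi_level"] = levels
    return out


def pi_level_order(levels=PI_LEVELS) -> list[str]:
    return list(levels)
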
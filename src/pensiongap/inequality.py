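"""Inequality statistics: relative mortality, improvements, LE-gap trends.

The relative mortality ratio RM of a PI group, for a 5-year age group and
period, is the ratio of the group's exposure-weighted graduated death rate to
the corresponding rate of the pensioner population as a whole:

    RM = q(group) / q(total),   q(bin) = sum_x E_x q_x / sum_x E_x.

RM = 1 means the group dies at the rate of its age group as a whole; the
column "Dif Low-High" (RM_Low - RM_High) summarises the mortality gradient.

Mortality improvements between two periods compare exposure-weighted
graduated rates: improvement = 100 * (1 - weighted(later) / weighted(earlier)),
positive when mortality fell, negative when it deteriorated.  The weights are
the earlier period's exposures by default (a fixed, Laspeyres-style standard);
``weight_period="later"`` switches the convention.

The LE-gap trend summarises, per period, the High-minus-Low gap in life
expectancy and its ordinary least-squares slope over the period index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graduate import GraduatedRateTable
from .tabulate import AGE_MAX, AGE_MIN, ExposureDeathTable

TOTAL = "Total"


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered 5-year age bins over 65-101; the last bin pools 85-101.

    ``bins`` maps label -> (lo, hi) inclusive single-age bounds; a ``Total``
    pseudo-bin spans the full range.
    """

    bins: tuple = (
        ("65-69", 65, 69),
        ("70-74", 70, 74),
        ("75-79", 75, 79),
        ("80-84", 80, 84),
        ("85+", 85, AGE_MAX),
    )

    def __post_init__(self) -> None:
        covered = sorted(x for _, lo, hi in self.bins for x in range(lo, hi + 1))
        if covered != list(range(AGE_MIN, AGE_MAX + 1)):
            raise ValueError("age bins must partition the 65-101 range")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.bins]

    def mask(self, ages: np.ndarray, label: str) -> np.ndarray:
        if label == TOTAL:
            return np.ones_like(ages, dtype=bool)
        lo, hi = {lab: (lo, hi) for lab, lo, hi in self.bins}[label]
        return (ages >= lo) & (ages <= hi)


def weighted_bin_rate(ages, q, exposure, scheme: AgeGroupScheme, label: str) -> float:
    """Exposure-weighted mean death rate over one age bin."""
    ages = np.asarray(ages)
    q = np.asarray(q, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    m = scheme.mask(ages, label)
    etot = exposure[m].sum()
    if etot <= 0:
        raise ValueError(f"no exposure in age bin {label}")
    return float(np.sum(exposure[m] * q[m]) / etot)


class RelativeMortalityTable:
    """RM per (age group, PI level, period) plus the Dif Low-High column.

    ``data`` is wide: index (period, age_group), one column per PI level and
    ``dif_low_high``.  Values are kept at full precision;
    :meth:`presentation` rounds the RMs to 2 decimals and recomputes the
    difference from the rounded values, as the ratios are reported.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data

    @classmethod
    def from_rm(cls, rm: pd.DataFrame) -> "RelativeMortalityTable":
        """Build from a wide frame of RM values (columns = PI levels)."""
        out = rm.copy()
        if "Low" in out.columns and "High" in out.columns:
            out["dif_low_high"] = out["Low"] - out["High"]
        return cls(out)

    def presentation(self) -> pd.DataFrame:
        out = self.data.drop(columns="dif_low_high", errors="ignore").round(2)
        if "Low" in out.columns and "High" in out.columns:
            out["dif_low_high"] = (out["Low"] - out["High"]).round(2)
        return out


def relative_mortality(
    rates: GraduatedRateTable,
    exposures: ExposureDeathTable,
    scheme: AgeGroupScheme | None = None,
    total_mode: str = "pooled",
) -> RelativeMortalityTable:
    """Relative mortality ratios by age group, PI level and period.

    ``total_mode`` selects the denominator rate: ``"pooled"`` uses the
    graduated rates of the pooled Total series (the default), ``"weighted"``
    uses the exposure-weighted mean of the group rates (under which the
    exposure-weighted mean RM is exactly 1 in every bin).
    """
    scheme = scheme or AgeGroupScheme()
    if total_mode not in ("pooled", "weighted"):
        raise ValueError(f"unknown total_mode {total_mode!r}")
    levels = [lv for lv in exposures.levels if lv != TOTAL]
    records = {}
    for period in exposures.periods:
        group_E = {}
        group_q = {}
        for level in levels + [TOTAL]:
            ages, E, _ = exposures.slice(level, period)
            group_E[level] = E
            group_q[level] = rates.q(level, period)
        for label in scheme.labels + [TOTAL]:
            row = {}
            for level in levels:
                row[level] = weighted_bin_rate(ages, group_q[level], group_E[level], scheme, label)
            if total_mode == "pooled":
                denom = weighted_bin_rate(ages, group_q[TOTAL], group_E[TOTAL], scheme, label)
            else:
                m = scheme.mask(ages, label)
                num = sum(np.sum(group_E[lv][m] * group_q[lv][m]) for lv in levels)
                den = sum(np.sum(group_E[lv][m]) for lv in levels)
                denom = num / den
            records[(period, label)] = {lv: row[lv] / denom for lv in levels}
    data = pd.DataFrame.from_dict(records, orient="index")
    data.index = pd.MultiIndex.from_tuples(data.index, names=["period", "age_group"])
    return RelativeMortalityTable.from_rm(data)


def mortality_improvement(
    rates_earlier, rates_later, weights
) -> float:
    """Percent improvement between two rate schedules under fixed weights.

    ``100 * (1 - sum(w q_later) / sum(w q_earlier))``; positive when the
    later period's weighted rate is lower (an improvement), negative when
    mortality deteriorated.
    """
    qa = np.asarray(rates_earlier, dtype=float)
    qb = np.asarray(rates_later, dtype=float)
    w = np.asarray(weights, dtype=float)
    denom = float(np.sum(w * qa))
    if denom <= 0:
        raise ValueError("zero weighted rate in the earlier period")
    return float(100.0 * (1.0 - np.sum(w * qb) / denom))


def improvement_table(
    rates: GraduatedRateTable,
    exposures: ExposureDeathTable,
    period_pairs: list[tuple[str, str]] | None = None,
    scheme: AgeGroupScheme | None = None,
    weight_period: str = "earlier",
) -> pd.DataFrame:
    """Mortality improvements (%) by age group, PI level and period pair."""
    scheme = scheme or AgeGroupScheme()
    if weight_period not in ("earlier", "later"):
        raise ValueError(f"unknown weight_period {weight_period!r}")
    periods = exposures.periods
    if period_pairs is None:
        period_pairs = [(a, b) for i, a in enumerate(periods) for b in periods[i + 1 :]]
    levels = [lv for lv in exposures.levels if lv != TOTAL] + [TOTAL]
    rows = []
    for pa, pb in period_pairs:
        for level in levels:
            ages, Ea, _ = exposures.slice(level, pa)
            _, Eb, _ = exposures.slice(level, pb)
            qa = rates.q(level, pa)
            qb = rates.q(level, pb)
            W = Ea if weight_period == "earlier" else Eb
            for label in scheme.labels + [TOTAL]:
                m = scheme.mask(ages, label)
                rows.append(
                    {
                        "period_pair": f"{pa}-{pb}",
                        "age_group": label,
                        "pi_level": level,
                        "improvement_pct": mortality_improvement(qa[m], qb[m], W[m]),
                    }
                )
    return pd.DataFrame(rows)


def gap_trend(le_summary: pd.DataFrame, age: int = 65) -> dict:
    """Per-period High-minus-Low LE gaps and their OLS slope.

    ``le_summary`` needs columns ``pi_level, period, age, le`` (the layout
    produced by the pipeline).  Returns ``{"gaps": {period: gap}, "slope":
    years per period step}``.
    """
    sub = le_summary[le_summary["age"] == age]
    periods = list(dict.fromkeys(sub["period"]))
    if len(periods) < 2:
        raise ValueError("need at least 2 periods for a trend")
    gaps = {}
    for period in periods:
        p = sub[sub["period"] == period].set_index("pi_level")["le"]
        gaps[period] = float(p["High"] - p["Low"])
    x = np.arange(len(periods), dtype=float)
    y = np.array([gaps[p] for p in periods])
    slope = float(np.polyfit(x, y, 1)[0])
    return {"gaps": gaps, "slope": slope}


def percent_excess(a: float, b: float, decimals: int = 0) -> float:
    """How much larger ``a`` is than ``b``, in percent (rounded)."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (a / b - 1.0), decimals) if decimals else round(100.0 * (a / b - 1.0))
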
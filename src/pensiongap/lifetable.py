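"""Complete period life tables over ages 65-101 and life-expectancy inference.

A standard period life-table recursion with radix l_65 = 100,000 and
separation factor a_x = 0.5 for ages 65-100.  The table closes out at 101:
q_101 = 1 and the final person-years are L_101 = l_101 / m_101, the standard
open-age-interval closeout (the 101 cell pools all exposure and deaths above
101, so 1/m_101 estimates the remaining expectancy there).  When no closeout
rate is available the expectancy of the open interval defaults to 1.0 year.

The sampling variance of LE follows Chiang's method: each graduated death
probability gets var(q_x) = q_x^2 (1 - q_x) / D_x with D_x = E_x * m_x the
estimated deaths at age x, and the per-age variances propagate through the
table as var(e_a) = sum_x l_x^2 (0.5 + e_{x+1})^2 var(q_x) / l_a^2.
Confidence intervals are normal-approximation 95% intervals, and differences
in LE between groups are tested one-tailed with z = DLE / SE(DLE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tabulate import AGE_MAX, AGE_MIN, AGES

Z95 = 1.959963984540054
#: One-tailed normal critical values at 1%, 5% and 10%.
Z_FLAGS = (("1%", 2.326), ("5%", 1.645), ("10%", 1.282))


class LifeTable:
    """Period life table columns l_x, d_x, L_x, T_x, e_x over ages 65-101."""

    def __init__(self, q, ages=None, radix: float = 100_000.0, m_closeout: float | None = None):
        self.ages = np.asarray(AGES if ages is None else ages, dtype=int)
        q = np.asarray(q, dtype=float).copy()
        if len(q) != len(self.ages):
            raise ValueError("q must cover every age of the table")
        if (q < 0).any() or (q > 1).any() or not np.isfinite(q).all():
            raise ValueError("death probabilities must lie in [0, 1]")
        q[-1] = 1.0  # closeout
        self.q = q
        self.radix = radix
        if m_closeout is not None and m_closeout > 0:
            self.a_closeout = 1.0 / m_closeout
        else:
            self.a_closeout = 1.0

        n = len(q)
        l = np.empty(n)
        l[0] = radix
        l[1:] = radix * np.cumprod(1.0 - q[:-1])
        d = l * q
        L = l - 0.5 * d
        L[-1] = l[-1] * self.a_closeout
        T = np.cumsum(L[::-1])[::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(l > 0, T / l, 0.0)
        self.l, self.d, self.L, self.T, self.e = l, d, L, T, e

    def expectancy(self, age: int) -> float:
        """Remaining life expectancy at exact ``age``."""
        idx = int(np.searchsorted(self.ages, age))
        if idx >= len(self.ages) or self.ages[idx] != age:
            raise ValueError(f"age {age} not in table")
        return float(self.e[idx])

    @property
    def le65(self) -> float:
        return self.expectancy(65)

    @property
    def le75(self) -> float:
        return self.expectancy(75)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "q": self.q,
                "l": self.l,
                "d": self.d,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )


def build_life_table(q, ages=None, radix: float = 100_000.0, m_closeout: float | None = None) -> LifeTable:
    """Build a :class:`LifeTable` from death probabilities over ages 65-101."""
    return LifeTable(q, ages=ages, radix=radix, m_closeout=m_closeout)


def chiang_variance(
    q, effective_deaths, table: LifeTable, start_age: int = 65
) -> float:
    """Variance of LE at ``start_age`` by Chiang's weighting of q variances.

    ``effective_deaths`` are the estimated death counts D_x = E_x * m_x per
    age; var(q_x) = q_x^2 (1-q_x) / D_x (zero where no deaths are expected).
    The open closeout age carries no q-variance term (q_101 = 1 by
    construction and its contribution is negligible at these radices).
    """
    q = np.asarray(q, dtype=float)
    D = np.asarray(effective_deaths, dtype=float)
    if len(q) != len(table.ages) or len(D) != len(table.ages):
        raise ValueError("q and effective_deaths must cover every age of the table")
    if (D <= 0).all():
        raise ValueError("all effective death counts are zero; variance undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        var_q = np.where(D > 0, q**2 * (1.0 - q) / D, 0.0)
    i0 = int(np.searchsorted(table.ages, start_age))
    if table.ages[i0] != start_age:
        raise ValueError(f"age {start_age} not in table")
    idx = np.arange(i0, len(table.ages) - 1)  # closeout age excluded
    w = table.l[idx] ** 2 * (0.5 + table.e[idx + 1]) ** 2
    var = float(np.sum(w * var_q[idx]) / table.l[i0] ** 2)
    return max(var, 0.0)


@dataclass(frozen=True)
class LEEstimate:
    """Life expectancy at one age for one PI group and period, with its CI."""

    pi_level: str
    period: str
    age: int
    le: float
    var: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var))

    @property
    def ci_lo(self) -> float:
        return self.le - Z95 * self.se

    @property
    def ci_hi(self) -> float:
        return self.le + Z95 * self.se


@dataclass(frozen=True)
class LEDifference:
    """One-tailed test of DLE = LE_a - LE_b > 0 between two PI groups."""

    group_a: str
    group_b: str
    period: str
    age: int
    dle: float
    se: float

    @property
    def z(self) -> float:
        return self.dle / self.se if self.se > 0 else 0.0

    @property
    def significance(self) -> str:
        """Most stringent one-tailed level at which the null is rejected ('' if none)."""
        for label, crit in Z_FLAGS:
            if self.z > crit:
                return label
        return ""

    def significant_at(self, label: str) -> bool:
        crit = dict(Z_FLAGS)[label]
        return self.z > crit


def test_le_difference(summary_a: LEEstimate, summary_b: LEEstimate) -> LEDifference:
    """Test the null of equal LE against LE_a > LE_b (one-tailed normal)."""
    if summary_a.age != summary_b.age or summary_a.period != summary_b.period:
        raise ValueError(
            f"cannot compare LE at age {summary_a.age}/{summary_b.age} in "
            f"periods {summary_a.period}/{summary_b.period}"
        )
    dle = summary_a.le - summary_b.le
    se = float(np.sqrt(summary_a.var + summary_b.var))
    return LEDifference(
        summary_a.pi_level, summary_b.pi_level, summary_a.period, summary_a.age, dle, se
    )


def le_from_rates(m, ages=None, radix: float = 100_000.0) -> LifeTable:
    """Life table straight from central rates (q = 1 - exp(-m), closeout from m)."""
    m = np.asarray(m, dtype=float)
    q = 1.0 - np.exp(-m)
    return build_life_table(q, ages=ages, radix=radix, m_closeout=float(m[-1]))


def bootstrap_le_distribution(
    E_matrix: np.ndarray,
    D_matrix: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    start_age: int = 65,
    lambda_: float | None = None,
    settings=None,
) -> np.ndarray:
    """Nonparametric bootstrap of graduated LE over individual records.

    ``E_matrix``/``D_matrix`` are per-record exposure and death matrices (see
    :func:`pensiongap.tabulate.exposure_death_matrices`).  Each replicate
    resamples records with replacement, re-tabulates, re-graduates (at a
    fixed smoothing parameter when ``lambda_`` is given, mirroring the point
    estimate) and rebuilds the life table.
    """
    from .graduate import PSplinePoissonSmoother

    n = E_matrix.shape[0]
    out = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, n, size=n)
        Eb = E_matrix[idx].sum(axis=0)
        Db = D_matrix[idx].sum(axis=0)
        fit = PSplinePoissonSmoother(Db, Eb, settings=settings).fit(lambda_)
        lt = le_from_rates(fit.m_grad)
        out[r] = lt.expectancy(start_age)
    return out
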
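"""Graduation of crude death rates.

Two smoothers over the bounded age range 65-101:

* :class:`PSplinePoissonSmoother` — penalized B-spline Poisson regression
  (P-splines): deaths D_x ~ Poisson(E_x * exp(eta_x)) with eta a cubic
  B-spline expansion on equidistant knots and a difference penalty of order 2
  on the coefficients.  The smoothing parameter is chosen by minimizing BIC
  over a log-spaced grid; the fit is by iteratively reweighted least squares.
  This is the primary estimator of the graduated central rates m_x.
* :func:`beta_kernel_graduate` — a discrete beta kernel smoother of the
  crude rates, whose kernel lives on the normalized age interval [0, 1] and
  adapts its shape near the boundaries; used as a robustness check.

Central rates convert to death probabilities via q = 1 - exp(-m), i.e. a
constant force of mortality within each year of age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import beta as beta_dist

from .tabulate import AGES, ExposureDeathTable

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries per-iteration diagnostics."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def m_to_q(m: np.ndarray) -> np.ndarray:
    """Central rate -> death probability under constant force within the year."""
    return 1.0 - np.exp(-np.asarray(m, dtype=float))


@dataclass
class GraduationSettings:
    """Knot layout, penalty and optimisation settings for the P-spline fit.

    Defaults: one interior knot every 2 years of age, cubic degree,
    second-order difference penalty, BIC-selected smoothing parameter.
    """

    knot_spacing: float = 2.0
    degree: int = 3
    penalty_order: int = 2
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-4.0, 7.0, 23))
    max_iter: int = 200
    tol: float = 1e-6


@dataclass
class PSplineFit:
    """Result of a P-spline graduation: rates, smoothing metadata, diagnostics."""

    ages: np.ndarray
    m_grad: np.ndarray
    q_grad: np.ndarray
    coef: np.ndarray
    lambda_: float
    bic: float
    edf: float
    deviance: float
    fitted_deaths: np.ndarray
    converged: bool
    n_iter: int


class PSplinePoissonSmoother:
    """Penalized Poisson B-spline model for one (group, period) rate series.

    Parameters
    ----------
    deaths, exposure : arrays over ``ages``
        Observed death counts and person-years; ages with zero exposure are
        excluded from the likelihood but still receive fitted rates.
    ages : array of int
        Single years of age (default the 65-101 range).
    settings : GraduationSettings
    """

    def __init__(self, deaths, exposure, ages=None, settings: GraduationSettings | None = None):
        self.ages = np.asarray(AGES if ages is None else ages, dtype=float)
        self.deaths = np.asarray(deaths, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        if not (len(self.ages) == len(self.deaths) == len(self.exposure)):
            raise ValueError("deaths, exposure and ages must have equal length")
        self.settings = settings or GraduationSettings()
        self._obs = self.exposure > 0
        if self._obs.sum() < 5:
            raise ValueError(
                f"need >= 5 ages with positive exposure, got {int(self._obs.sum())}"
            )
        self._basis, self._knots = self._build_basis()
        self._penalty = self._build_penalty()

    def _build_basis(self) -> tuple[np.ndarray, np.ndarray]:
        s, k = self.settings.knot_spacing, self.settings.degree
        x0, x1 = self.ages.min(), self.ages.max()
        n_inner = int(np.ceil((x1 - x0) / s))
        inner = x0 + s * np.arange(n_inner + 1)
        knots = np.concatenate(
            [x0 + s * np.arange(-k, 0), inner, inner[-1] + s * np.arange(1, k + 1)]
        )
        basis = BSpline.design_matrix(self.ages, knots, k, extrapolate=True).toarray()
        return basis, knots

    def _build_penalty(self) -> np.ndarray:
        ncoef = self._basis.shape[1]
        D = np.diff(np.eye(ncoef), n=self.settings.penalty_order, axis=0)
        return D.T @ D

    def _fit_one(self, lam: float):
        st = self.settings
        obs = self._obs
        B = self._basis[obs]
        y = self.deaths[obs]
        E = self.exposure[obs]
        eta = np.log((y + 0.5) / E)
        beta_c, *_ = np.linalg.lstsq(B, eta, rcond=None)
        history: list[float] = []
        converged = False
        for it in range(1, st.max_iter + 1):
            eta = np.clip(B @ beta_c, -40.0, 10.0)
            mu = E * np.exp(eta)
            W = mu
            z = eta + y / mu - 1.0
            lhs = (B * W[:, None]).T @ B + lam * self._penalty
            rhs = (B * W[:, None]).T @ z
            try:
                beta_new = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                # weights collapsed (diverging step): treat as non-convergence
                history.append(float("inf"))
                break
            change = np.max(np.abs(beta_new - beta_c) / (np.abs(beta_c) + 1e-8))
            history.append(float(change))
            beta_c = beta_new
            if change < st.tol:
                converged = True
                break
        eta = np.clip(B @ beta_c, -40.0, 10.0)
        mu = E * np.exp(eta)
        BtWB = (B * mu[:, None]).T @ B
        try:
            edf = float(np.trace(np.linalg.solve(BtWB + lam * self._penalty, BtWB)))
        except np.linalg.LinAlgError:
            edf = float("nan")
            converged = False
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        deviance = float(2.0 * dev_terms.sum())
        return beta_c, edf, deviance, converged, it, history

    def fit(self, lambda_: float | None = None) -> PSplineFit:
        """Fit the model; BIC-select the smoothing parameter if not given."""
        if lambda_ is None:
            best = None
            for lam in self.settings.lambda_grid:
                res = self._try_fit(lam)
                if res is None:
                    continue
                if best is None or res.bic < best.bic:
                    best = res
            if best is None:
                raise ConvergenceError(
                    "IRLS failed to converge for every smoothing parameter on the grid",
                    [],
                )
            return best
        res = self._try_fit(lambda_, strict=True)
        return res

    def _try_fit(self, lam: float, strict: bool = False) -> PSplineFit | None:
        beta_c, edf, deviance, converged, n_iter, history = self._fit_one(lam)
        if not converged:
            if self.deaths[self._obs].sum() == 0:
                logger.warning("all-zero death counts: returning penalized fit as-is")
            elif strict:
                raise ConvergenceError(
                    f"IRLS did not converge in {self.settings.max_iter} iterations "
                    f"(lambda={lam:g}, last relative change {history[-1]:.3e})",
                    history,
                )
            else:
                return None
        n_obs = int(self._obs.sum())
        bic = deviance + np.log(n_obs) * edf
        eta_all = np.clip(self._basis @ beta_c, -40.0, 10.0)
        m = np.exp(eta_all)
        return PSplineFit(
            ages=self.ages.astype(int),
            m_grad=m,
            q_grad=m_to_q(m),
            coef=beta_c,
            lambda_=float(lam),
            bic=float(bic),
            edf=edf,
            deviance=deviance,
            fitted_deaths=self.exposure * m,
            converged=converged,
            n_iter=n_iter,
        )


def pspline_graduate(
    deaths, exposure, ages=None, settings: GraduationSettings | None = None
) -> PSplineFit:
    """Convenience wrapper: build the smoother and fit with BIC selection."""
    return PSplinePoissonSmoother(deaths, exposure, ages, settings).fit()


def beta_kernel_graduate(
    deaths, exposure, ages=None, bandwidth: float | None = None,
    bandwidth_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete beta kernel graduation of crude rates over a bounded age range.

    The graduated rate at age x is a kernel-weighted average of the crude
    rates D/E, the kernel being a beta density on the normalized age interval
    [0, 1] with mode at x.  The boundary bias of symmetric kernels is avoided
    because the beta shape adapts near 0 and 1.  ``bandwidth`` -> 0
    degenerates to the crude rates.  If no bandwidth is given it is chosen by
    leave-one-out cross-validation (exposure-weighted squared error).
    """
    ages = np.asarray(AGES if ages is None else ages, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    obs = exposure > 0
    crude = np.zeros_like(ages)
    crude[obs] = deaths[obs] / exposure[obs]
    span = ages.max() - ages.min()
    u = (ages - ages.min()) / span  # normalized ages

    def weights(b: float) -> np.ndarray:
        # rows: target age, cols: observed age
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = beta_dist.pdf(u[None, :], u[:, None] / b + 1.0, (1.0 - u[:, None]) / b + 1.0)
        W[:, ~obs] = 0.0
        return W

    def smooth(b: float) -> np.ndarray:
        W = weights(b)
        rows = W.sum(axis=1)
        out = np.where(rows > 0, (W @ crude) / np.where(rows > 0, rows, 1.0), crude)
        return out

    if bandwidth is None:
        grid = np.logspace(-2.5, 0.5, 25) if bandwidth_grid is None else bandwidth_grid
        best_b, best_score = None, np.inf
        idx = np.flatnonzero(obs)
        for b in grid:
            W = weights(b)
            np.fill_diagonal(W, 0.0)
            rows = W.sum(axis=1)
            ok = rows[idx] > 0
            loo = (W @ crude)[idx][ok] / rows[idx][ok]
            score = float(np.sum(exposure[idx][ok] * (crude[idx][ok] - loo) ** 2))
            if score < best_score:
                best_b, best_score = float(b), score
        bandwidth = best_b
    return smooth(bandwidth)


class GraduatedRateTable:
    """Graduated rates per (age, pi_level, period) with smoothing metadata.

    ``data`` columns: ``age, pi_level, period, m_grad, q_grad, lambda, criterion``.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)

    def slice(self, pi_level: str, period: str) -> pd.DataFrame:
        sub = self.data[
            (self.data["pi_level"] == pi_level) & (self.data["period"] == period)
        ]
        return sub.sort_values("age").reset_index(drop=True)

    def q(self, pi_level: str, period: str) -> np.ndarray:
        return self.slice(pi_level, period)["q_grad"].to_numpy()

    def m(self, pi_level: str, period: str) -> np.ndarray:
        return self.slice(pi_level, period)["m_grad"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "GraduatedRateTable":
        return cls(pd.read_csv(path))


def graduate_table(
    table: ExposureDeathTable,
    settings: GraduationSettings | None = None,
    method: str = "pspline",
    bandwidth: float | None = None,
) -> GraduatedRateTable:
    """Graduate every (group, period) series of an ExposureDeathTable.

    The ``Total`` pseudo-group is graduated from its own pooled deaths and
    exposures, not by averaging group fits.
    """
    rows = []
    for period in table.periods:
        for level in table.levels + ["Total"]:
            ages, E, D = table.slice(level, period)
            if method == "pspline":
                fit = pspline_graduate(D, E, ages, settings)
                m, lam, crit = fit.m_grad, fit.lambda_, fit.bic
            elif method == "beta_kernel":
                m = beta_kernel_graduate(D, E, ages, bandwidth)
                lam, crit = float("nan") if bandwidth is None else bandwidth, float("nan")
            else:
                raise ValueError(f"unknown graduation method {method!r}")
            q = m_to_q(m)
            for age, mm, qq in zip(ages, m, q):
                rows.append(
                    {
                        "age": int(age),
                        "pi_level": level,
                        "period": period,
                        "m_grad": float(mm),
                        "q_grad": float(qq),
                        "lambda": lam,
                        "criterion": crit,
                    }
                )
    return GraduatedRateTable(pd.DataFrame(rows))
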
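"""Exponential kinetics of body formation and dissociation.

Time courses record, per timepoint, how many of the inspected cells contain
at least one body.  Replicate fractions are averaged and the mean series is
fit by unweighted nonlinear least squares to

    formation:    f(t) = A * (1 - exp(-t / tau)) + c
    dissociation: f(t) = A * exp(-t / tau) + c

where A is the fraction of cells that change state during the time course,
tau the apparent time constant (minutes) and c the baseline fraction (at the
start for formation, at the end for dissociation).  Conditions with no
change over time are fit to a straight line instead.  Model choice is the
caller's, mirroring the per-condition choice made when such data are
presented; an F-test helper is available but never applied automatically.

Standard errors are the square roots of the diagonal of the covariance of
the fit.  Optimization uses bounded least squares with multi-start
initialization over tau so convergence is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats

_GRID_TOL = 1e-9


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


@dataclass(frozen=True)
class TimecoursePoint:
    time_min: float
    n_cells: int
    n_with_bodies: int

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if not 0 <= self.n_with_bodies <= self.n_cells:
            raise ValueError("need 0 <= n_with_bodies <= n_cells")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")

    @property
    def fraction(self) -> float:
        return self.n_with_bodies / self.n_cells


@dataclass
class TimecourseDataset:
    """Replicated body-positive counts on a shared timepoint grid."""

    replicates: list[list[TimecoursePoint]]
    condition: str = ""
    strain: str = ""
    truth: object | None = None  # generating parameters, when simulated

    def __post_init__(self) -> None:
        if not self.replicates or not self.replicates[0]:
            raise ValueError("need at least one replicate with data")
        grid = self.times
        for rep in self.replicates[1:]:
            other = np.array([p.time_min for p in rep])
            if len(other) != len(grid) or np.any(np.abs(other - grid) > _GRID_TOL):
                raise ValueError("replicates must share the same timepoint grid")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_min for p in self.replicates[0]])

    @property
    def fractions(self) -> np.ndarray:
        """(n_replicates, n_timepoints) array of body-positive fractions."""
        return np.array([[p.fraction for p in rep] for rep in self.replicates])


@dataclass(frozen=True)
class FractionSeries:
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray  # NaN where undefined (single replicate)
    n_replicates: int


@dataclass(frozen=True)
class ExponentialFit:
    model: str  # "formation" | "dissociation"
    A: float
    tau: float
    c: float
    se_A: float
    se_tau: float
    se_c: float
    rss: float
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _MODELS[self.model](np.asarray(t, float), self.A, self.tau, self.c)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    rss: float
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, float)


def _formation(t, A, tau, c):
    return A * (1.0 - np.exp(-t / tau)) + c


def _dissociation(t, A, tau, c):
    return A * np.exp(-t / tau) + c


_MODELS: dict[str, Callable] = {"formation": _formation, "dissociation": _dissociation}


def mean_fraction_series(dataset: TimecourseDataset) -> FractionSeries:
    """Per-timepoint mean and sample standard deviation across replicates.

    The standard deviation uses the n-1 denominator and is NaN for a single
    replicate.
    """
    fr = dataset.fractions
    mean = fr.mean(axis=0)
    if fr.shape[0] > 1:
        sd = fr.std(axis=0, ddof=1)
    else:
        sd = np.full(fr.shape[1], np.nan)
    return FractionSeries(times=dataset.times, mean=mean, sd=sd, n_replicates=fr.shape[0])


def _fit_exponential(times, fractions, model: str) -> ExponentialFit:
    t = np.asarray(times, float)
    y = np.asarray(fractions, float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints for a 3-parameter fit")
    if len(np.unique(t)) < 3:
        raise ValueError("degenerate timepoint grid")
    f = _MODELS[model]
    t_max = float(t.max())
    if t_max <= 0:
        raise ValueError("all timepoints are zero")

    if model == "formation":
        a0 = np.clip(y[-1] - y[0], 0.0, 1.0)
        c0 = np.clip(y[0], 0.0, 1.0)
    else:
        a0 = np.clip(y[0] - y[-1], 0.0, 1.0)
        c0 = np.clip(y[-1], 0.0, 1.0)
    bounds = ([0.0, 1e-9, 0.0], [1.0, 10.0 * t_max, 1.0])

    best = None
    diagnostics = []
    for tau0 in (t_max / 10.0, t_max / 3.0, t_max):
        try:
            popt, pcov = optimize.curve_fit(
                f, t, y, p0=[a0, tau0, c0], bounds=bounds, maxfev=20000
            )
        except (RuntimeError, optimize.OptimizeWarning) as err:  # non-convergence
            diagnostics.append(f"tau0={tau0:g}: {err}")
            continue
        rss = float(np.sum((f(t, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(
            f"{model} fit failed from every start; " + "; ".join(diagnostics)
        )
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    return ExponentialFit(
        model=model,
        A=float(popt[0]), tau=float(popt[1]), c=float(popt[2]),
        se_A=float(se[0]), se_tau=float(se[1]), se_c=float(se[2]),
        rss=rss, n_points=len(t),
    )


def fit_formation(times, fractions) -> ExponentialFit:
    """Fit A*(1 - e^(-t/tau)) + c to a mean-fraction series."""
    return _fit_exponential(times, fractions, "formation")


def fit_dissociation(times, fractions) -> ExponentialFit:
    """Fit A*e^(-t/tau) + c to a mean-fraction series."""
    return _fit_exponential(times, fractions, "dissociation")


def fit_flat(times, fractions) -> LinearFit:
    """Ordinary least-squares line for conditions with no kinetic change."""
    t = np.asarray(times, float)
    y = np.asarray(fractions, float)
    if len(t) < 2:
        raise ValueError("need at least 2 timepoints for a line")
    X = np.column_stack([np.ones_like(t), t])
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = len(t) - 2
    if dof > 0 and len(np.unique(t)) > 1:
        s2 = rss / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([np.nan, np.nan])
    return LinearFit(
        slope=float(beta[1]), intercept=float(beta[0]),
        se_slope=float(se[1]), se_intercept=float(se[0]),
        rss=rss, n_points=len(t),
    )


def compare_exponential_vs_flat(times, fractions, model: str = "formation"):
    """Optional F-test of the 3-parameter exponential against the 2-parameter line.

    Returns (F, p).  Provided for exploration only; model choice stays with
    the caller.
    """
    expo = _fit_exponential(times, fractions, model)
    line = fit_flat(times, fractions)
    n = len(np.asarray(times))
    df1, df2 = 1, n - 3
    if df2 <= 0 or expo.rss <= 0:
        return np.nan, np.nan
    F = (line.rss - expo.rss) / df1 / (expo.rss / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p
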
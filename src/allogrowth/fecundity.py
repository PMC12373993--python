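"""Lifetime fecundity from the fitted growth/allocation model.

The cumulative energy routed to direct reproduction up to age tau is

    g_tau = q * integral_0^tau r_u l_u^lambda du,

with l_u the model-implied length curve (numerical solution of the fitted
ODE).  Assuming a roughly constant energy cost per neonate, the cumulative
neonate count is proportional to g_tau; the proportionality constant is
fitted by least squares through the origin against the observed cumulative
brood counts, giving the scaled curve N_hat(tau) and the Table-style
summaries (mean lifespan tau_hat and N_hat at tau_hat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .gradient_fit import FitResult, GrowthDataset
from .growth_model import simulate_length

__all__ = [
    "FecundityCurve",
    "LifetimeSummary",
    "cumulative_reproduction",
    "scale_to_counts",
    "scale_to_counts_arrays",
    "scale_to_counts_shared",
    "mean_lifetime",
    "neonates_at",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass
class FecundityCurve:
    """Cumulative reproduction energy and its neonate-count scaling."""

    tau_grid: np.ndarray
    g: np.ndarray                      # cumulative energy, g(0) = 0
    scale_const: Optional[float] = None   # neonates per energy unit
    scenario: str = ""

    @property
    def n_hat(self) -> np.ndarray:
        if self.scale_const is None:
            raise ValueError("curve is unscaled; run scale_to_counts first")
        return self.scale_const * self.g


@dataclass
class LifetimeSummary:
    scenario: str
    tau_hat: float
    n_at_tau: float
    tau_ci: Optional[tuple[float, float]] = None
    n_ci: Optional[tuple[float, float]] = None


def cumulative_reproduction(fit: FitResult, scenario: str,
                            tau_grid, length_at=None) -> FecundityCurve:
    """Unscaled cumulative reproduction energy q * int r_u l_u^lambda du.

    The length curve inside the integral is the numerical solution of the
    fitted ODE started from the scenario's mean birth length; pass
    ``length_at`` (a callable age -> length, e.g. a loess curve) to
    integrate along an empirical curve instead.  The integral is
    accumulated with the trapezium rule on a fine internal grid.  Beyond
    the support of the fitted r_t curve the last r value is held (with a
    logged warning).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.ndim != 1 or tau_grid.size < 2 or tau_grid[0] != 0:
        raise ValueError("tau_grid must start at 0 with at least 2 points")
    if np.any(np.diff(tau_grid) <= 0):
        raise ValueError("tau_grid must be strictly increasing")
    sched = fit.r_hat[scenario]
    if tau_grid[-1] > sched.times[-1] + 1e-9:
        logger.warning("scenario %s: tau grid extends past the fitted r_t "
                       "support (%.3g > %.3g); holding the last r value",
                       scenario, tau_grid[-1], sched.times[-1])
    step = min(0.1, float(np.min(np.diff(tau_grid))))
    if length_at is None:
        traj = simulate_length(fit.growth_params(scenario), sched,
                               fit.l0[scenario], t_end=float(tau_grid[-1]),
                               step=step)
        times, lengths = traj.times, traj.lengths
    else:
        times = np.arange(0.0, tau_grid[-1] + step, step)
        lengths = np.asarray(length_at(times), dtype=float)
    # accumulate on the fine grid, then read off at tau_grid, so a coarse
    # output grid does not coarsen the quadrature
    integrand = (fit.q_hat[scenario] * sched(times)
                 * lengths ** fit.lambda_hat)
    g_fine = cumulative_trapezoid(integrand, times, initial=0.0)
    g = np.interp(tau_grid, times, g_fine)
    return FecundityCurve(tau_grid=tau_grid, g=g, scenario=scenario)


def scale_to_counts_arrays(curve: FecundityCurve, brood_times,
                           cum_counts) -> FecundityCurve:
    """Least-squares-through-origin scaling against pooled cumulative counts.

    c = sum(N_obs * g) / sum(g^2) over all (individual, brood time) pairs.
    """
    brood_times = np.asarray(brood_times, dtype=float)
    cum_counts = np.asarray(cum_counts, dtype=float)
    if brood_times.size == 0:
        raise ValueError("no brood records to scale against")
    g_at = np.interp(brood_times, curve.tau_grid, curve.g)
    denom = float(np.sum(g_at * g_at))
    if denom <= 0:
        raise ValueError("cumulative energy is zero at all brood times; "
                         "cannot scale")
    c = float(np.sum(cum_counts * g_at) / denom)
    return FecundityCurve(tau_grid=curve.tau_grid, g=curve.g, scale_const=c,
                          scenario=curve.scenario)


def scale_to_counts(curve: FecundityCurve, dataset: GrowthDataset,
                    scenario: str) -> FecundityCurve:
    """Scale an energy curve to neonate counts using a scenario's broods."""
    br = dataset.cumulative_broods(scenario)
    if br.empty:
        raise ValueError(f"scenario {scenario!r} has no brood records")
    return scale_to_counts_arrays(curve, br["time_days"].to_numpy(),
                                  br["cum_neonates"].to_numpy())


def scale_to_counts_shared(curves: dict[str, FecundityCurve],
                           dataset: GrowthDataset) -> dict[str, FecundityCurve]:
    """One shared neonates-per-energy constant across all scenarios.

    Pools every scenario's (cumulative count, cumulative energy) pairs into
    a single least-squares-through-origin fit and applies the common
    constant to each curve.
    """
    num = den = 0.0
    for scen, curve in curves.items():
        br = dataset.cumulative_broods(scen)
        if br.empty:
            continue
        g_at = np.interp(br["time_days"].to_numpy(), curve.tau_grid, curve.g)
        num += float(np.sum(br["cum_neonates"].to_numpy() * g_at))
        den += float(np.sum(g_at * g_at))
    if den <= 0:
        raise ValueError("no usable brood records across scenarios")
    c = num / den
    return {scen: FecundityCurve(tau_grid=curve.tau_grid, g=curve.g,
                                 scale_const=c, scenario=curve.scenario)
            for scen, curve in curves.items()}


def mean_lifetime(dataset: GrowthDataset, scenario: str) -> float:
    """Mean lifespan: average of per-individual last observation times."""
    deaths = dataset.death_times(scenario)
    if deaths.empty:
        raise ValueError(f"scenario {scenario!r} has no individuals")
    return float(deaths.mean())


def neonates_at(curve: FecundityCurve, tau: float) -> float:
    """Scaled cumulative neonate count at age tau (linear interpolation)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    n = curve.n_hat
    grid = curve.tau_grid
    if tau > grid[-1]:
        warnings.warn("tau beyond the fecundity grid; extrapolating with the "
                      "final slope", RuntimeWarning, stacklevel=2)
        slope = (n[-1] - n[-2]) / (grid[-1] - grid[-2])
        return float(n[-1] + slope * (tau - grid[-1]))
    return float(np.interp(tau, grid, n))


def summarize(fit: FitResult, dataset: GrowthDataset,
              tau_step: float = 0.25) -> pd.DataFrame:
    """Per-scenario summary table: q_hat, lambda_hat, N_hat(tau_hat), tau_hat.

    Confidence-interval columns are filled when ``fit`` carries bootstrap
    intervals.
    """
    rows = []
    for scen in fit.scenarios:
        tau = mean_lifetime(dataset, scen)
        t_hi = max(tau, float(fit.r_hat[scen].times[-1]))
        grid = np.arange(0.0, t_hi + tau_step, tau_step)
        curve = cumulative_reproduction(fit, scen, grid)
        curve = scale_to_counts(curve, dataset, scen)
        n_tau = neonates_at(curve, tau)
        ci = fit.ci or {}
        rows.append({
            "scenario": scen,
            "q_hat": fit.q_hat[scen],
            "lambda_hat": fit.lambda_hat,
            "n_tau_hat": n_tau,
            "tau_hat": tau,
            "q_lo": ci.get(f"q:{scen}", (np.nan, np.nan))[0],
            "q_hi": ci.get(f"q:{scen}", (np.nan, np.nan))[1],
            "lambda_lo": ci.get("lambda", (np.nan, np.nan))[0],
            "lambda_hi": ci.get("lambda", (np.nan, np.nan))[1],
            "n_tau_lo": ci.get(f"n_tau:{scen}", (np.nan, np.nan))[0],
            "n_tau_hi": ci.get(f"n_tau:{scen}", (np.nan, np.nan))[1],
            "tau_lo": ci.get(f"tau:{scen}", (np.nan, np.nan))[0],
            "tau_hi": ci.get(f"tau:{scen}", (np.nan, np.nan))[1],
        })
    return pd.DataFrame(rows)
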
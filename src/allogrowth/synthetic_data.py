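"""Synthetic Daphnia-style populations with known ground truth.

Four temperature scenarios — constant low (15 C), constant rearing (20 C),
constant high (25 C) and unpredictable variation (15-25 C) — each with a
known growth scalar q, shared length exponent lambda, a saturating
allocation schedule r(t) = r_max (1 - exp(-t/theta)), and scenario-specific
lifespans and brood cadence.  Individuals are observed only at birth, at
each brood and at death, so observation times are uneven and event-driven,
matching the structure of the real experiment's records.

Scenario defaults are calibrated so that the generated populations carry the
study's reported scales: growth scalars {0.118, 0.169, 0.209, 0.196},
exponent 0.179, mean lifespans {81, 72, 48, 52} days and lifetime neonate
counts around {239, 236, 181, 194} for (low, rearing, high, unpredictable);
the allocation curves rise faster at warmer temperatures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .gradient_fit import GrowthDataset
from .growth_model import AllocationSchedule, GrowthParams, _rk4_length

__all__ = [
    "SCENARIOS",
    "DEFAULT_COHORTS",
    "ScenarioTruth",
    "TemperatureSeries",
    "temperature_schedule",
    "scenario_truth",
    "generate_population",
    "generate_default_population",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

SCENARIOS = ("constant_low", "constant_rearing", "constant_high",
             "unpredictable")

#: cohort sizes of the emulated experiment (628 individuals in total)
DEFAULT_COHORTS = {"constant_low": 158, "constant_rearing": 156,
                   "constant_high": 157, "unpredictable": 157}

_TRUTH_TABLE = {
    # label: (q, lifespan, theta, r_max, maturation, brood_interval, n_tau)
    "constant_low":     (0.118, 81.0, 10.0, 0.85, 8.0, 4.0, 239.0),
    "constant_rearing": (0.169, 72.0, 7.0, 0.85, 6.0, 3.5, 236.0),
    "constant_high":    (0.209, 48.0, 4.5, 0.88, 4.5, 2.5, 181.0),
    "unpredictable":    (0.196, 52.0, 5.0, 0.87, 5.0, 3.0, 194.0),
}

LAMBDA_TRUE = 0.179


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground-truth generating parameters of one temperature scenario.

    The allocation schedule is r(t) = r_max (1 - exp(-t / theta)); theta
    shrinks with temperature so warmer scenarios commit to reproduction
    earlier.  ``neonate_rate`` converts cumulative reproduction energy into
    expected neonate counts.
    """

    label: str
    q_true: float
    lambda_true: float
    r_max: float
    theta: float
    mean_lifespan: float
    lifespan_cv: float
    maturation_age: float
    brood_interval: float
    l0_mean: float
    l0_cv: float
    obs_noise_cv: float
    neonate_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_max < 1:
            raise ValueError("r_max must lie in [0, 1)")
        if self.theta <= 0 or self.brood_interval <= 0:
            raise ValueError("theta and brood_interval must be positive")
        if min(self.lifespan_cv, self.l0_cv, self.obs_noise_cv) < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.q_true <= 0 or self.l0_mean <= 0 or self.neonate_rate < 0:
            raise ValueError("q_true and l0_mean must be positive")

    def r(self, t):
        return self.r_max * (1.0 - np.exp(-np.asarray(t, dtype=float)
                                          / self.theta))

    def schedule(self, t_end: float, step: float = 0.1) -> AllocationSchedule:
        times = np.arange(0.0, t_end + step, step)
        return AllocationSchedule(times=times, r=self.r(times))

    def growth_params(self) -> GrowthParams:
        return GrowthParams(q=self.q_true, lam=self.lambda_true)


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly-resolution temperature program of a scenario."""

    label: str
    hours: np.ndarray
    celsius: np.ndarray


def temperature_schedule(label: str, n_days: int, resolution_hours: int = 1,
                         seed: int | None = None) -> TemperatureSeries:
    """Temperature program over the experiment.

    Constant scenarios are flat at 15 / 20 / 25 C.  Under the unpredictable
    scenario the temperature is drawn independently and uniformly within the
    daily segment's band: 15-20 C from 00:00-08:00 and 18:00-24:00, 20-25 C
    from 08:00-18:00.  Independent uniform draws average about 19.6 C overall
    ((14 * 17.5 + 10 * 22.5) / 24); the study's own program reports 19.8 C,
    so its draws were evidently not uniform — the band structure, not the
    exact program, is emulated here.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if 24 % resolution_hours != 0:
        raise ValueError("resolution_hours must divide 24")
    hours = np.arange(0, 24 * n_days, resolution_hours, dtype=float)
    flat = {"constant_low": 15.0, "constant_rearing": 20.0,
            "constant_high": 25.0}
    if label in flat:
        return TemperatureSeries(label, hours, np.full(hours.size, flat[label]))
    if label != "unpredictable":
        raise ValueError(f"unknown scenario label {label!r}")
    rng = np.random.default_rng(seed)
    hod = hours % 24
    warm = (hod >= 8) & (hod < 18)
    lo = np.where(warm, 20.0, 15.0)
    celsius = lo + 5.0 * rng.random(hours.size)
    return TemperatureSeries(label, hours, celsius)


def _true_energy_at(q: float, lam: float, r_max: float, theta: float,
                    l0: float, tau: float, step: float = 0.05) -> float:
    """Cumulative reproduction energy q int_0^tau r l^lam du at the truth."""
    n = int(np.ceil(tau / step))
    times = np.linspace(0.0, tau, n + 1)
    half = np.linspace(0.0, tau, 2 * n + 1)
    r_half = r_max * (1.0 - np.exp(-half / theta))
    l = _rk4_length(q, lam, r_half, l0, tau / n, n)
    integrand = q * r_half[::2] * l ** lam
    return float(np.trapezoid(integrand, times))


@lru_cache(maxsize=None)
def scenario_truth(label: str) -> ScenarioTruth:
    """Default ground truth for a scenario label.

    ``neonate_rate`` is derived so that the expected cumulative count at the
    scenario's mean lifespan equals the scenario's lifetime-fecundity target
    (neonates = rate * cumulative energy).
    """
    if label not in _TRUTH_TABLE:
        raise ValueError(f"unknown scenario label {label!r}; "
                         f"expected one of {SCENARIOS}")
    q, lifespan, theta, r_max, maturation, interval, n_tau = _TRUTH_TABLE[label]
    l0_mean = 0.8
    energy = _true_energy_at(q, LAMBDA_TRUE, r_max, theta, l0_mean, lifespan)
    return ScenarioTruth(
        label=label, q_true=q, lambda_true=LAMBDA_TRUE, r_max=r_max,
        theta=theta, mean_lifespan=lifespan, lifespan_cv=0.15,
        maturation_age=maturation, brood_interval=interval,
        l0_mean=l0_mean, l0_cv=0.04, obs_noise_cv=0.03,
        neonate_rate=n_tau / energy)


def generate_population(truth: ScenarioTruth, n_individuals: int,
                        seed: int | None = None,
                        brood_jitter: float = 0.3) -> GrowthDataset:
    """Generate one scenario's cohort of event-driven growth records.

    Per individual: birth length lognormal around ``l0_mean``; lifespan
    gamma-distributed around ``mean_lifespan``; the true length curve is the
    RK4 solution of the growth ODE at the truth; brood times start at the
    maturation age and recur every ``brood_interval`` days (uniform jitter of
    +/- ``brood_jitter``); observations are taken at birth, each brood and
    death, with multiplicative lognormal measurement noise; brood sizes are
    Poisson with mean ``neonate_rate`` times the reproduction-energy
    increment since the previous brood.  Fully deterministic given the seed.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)

    def _lognormal(mean: float, cv: float, size=None):
        if cv == 0:
            return np.full(size, mean) if size else mean
        s2 = np.log1p(cv * cv)
        return rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), size)

    l0 = _lognormal(truth.l0_mean, truth.l0_cv, n_individuals)
    if truth.lifespan_cv == 0:
        lifespan = np.full(n_individuals, truth.mean_lifespan)
    else:
        shape = 1.0 / truth.lifespan_cv ** 2
        lifespan = rng.gamma(shape, truth.mean_lifespan / shape, n_individuals)
    lifespan = np.maximum(lifespan, truth.maturation_age + truth.brood_interval)

    # shared dense grid out to the oldest individual; all individuals share
    # (q, lambda, r), so the ODE is solved once as a vector over l0
    step = 0.05
    t_max = float(lifespan.max())
    n_steps = int(np.ceil(t_max / step))
    h = t_max / n_steps
    times = np.linspace(0.0, t_max, n_steps + 1)
    half = np.linspace(0.0, t_max, 2 * n_steps + 1)
    r_half = truth.r_max * (1.0 - np.exp(-half / truth.theta))
    curves = _rk4_length(truth.q_true, truth.lambda_true, r_half, l0, h,
                         n_steps)  # (n_steps+1, n_individuals)
    integrand = truth.q_true * r_half[::2, None] * curves ** truth.lambda_true
    energy = cumulative_trapezoid(integrand, times, axis=0, initial=0.0)

    rows = []
    for i in range(n_individuals):
        ind_id = f"{truth.label}_{i + 1:04d}"
        t_death = float(lifespan[i])
        broods = []
        t = truth.maturation_age
        while t < t_death - 0.5:
            jit = rng.uniform(-brood_jitter, brood_jitter)
            broods.append(min(max(t + jit, 0.1), t_death - 0.5))
            t += truth.brood_interval
        obs_times = np.concatenate([[0.0], np.sort(broods), [t_death]])
        true_l = np.interp(obs_times, times, curves[:, i])
        noise = _lognormal(1.0, truth.obs_noise_cv, obs_times.size)
        obs_l = true_l * noise
        g_at = np.interp(obs_times, times, energy[:, i])
        neonates = np.full(obs_times.size, np.nan)
        for j in range(1, obs_times.size - 1):
            dg = g_at[j] - g_at[j - 1]
            neonates[j] = rng.poisson(truth.neonate_rate * max(dg, 0.0))
        for t_obs, l_obs, n_obs in zip(obs_times, obs_l, neonates):
            rows.append((ind_id, truth.label, float(t_obs), float(l_obs),
                         float(n_obs) if np.isfinite(n_obs) else np.nan))

    frame = pd.DataFrame(rows, columns=["individual_id", "scenario",
                                        "time_days", "length_mm", "neonates"])
    return GrowthDataset(frame)


def generate_default_population(seed: int,
                                cohorts: dict[str, int] | None = None
                                ) -> tuple[GrowthDataset, dict[str, ScenarioTruth]]:
    """The default four-scenario population (628 individuals).

    Scenario sub-seeds are derived from ``seed`` so cohorts are independent
    but jointly reproducible.
    """
    cohorts = dict(DEFAULT_COHORTS if cohorts is None else cohorts)
    seq = np.random.SeedSequence(seed)
    frames, truths = [], {}
    for child, label in zip(seq.spawn(len(cohorts)), sorted(cohorts)):
        truth = scenario_truth(label)
        truths[label] = truth
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        frames.append(generate_population(truth, cohorts[label],
                                          seed=sub_seed).frame)
    return GrowthDataset(pd.concat(frames, ignore_index=True)), truths


def write_truth_sidecar(truths: dict[str, ScenarioTruth], path) -> None:
    """Write ground-truth parameters next to a generated dataset (JSON)."""
    payload = {label: asdict(t) for label, t in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_truth_sidecar(path) -> dict[str, ScenarioTruth]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {label: ScenarioTruth(**fields) for label, fields in payload.items()}
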
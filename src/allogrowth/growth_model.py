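"""Allometric energy-allocation growth model.

Body mass ``m_t`` is split into somatic mass ``s_t`` and gonadic mass
``g_t``::

    dm = ds + dg
    ds = a s^alpha dt - c s^gamma dt - dg
    dg = b s^beta dt

Energy acquisition scales as ``a s^alpha``, non-growth costs (maintenance and
indirect reproduction) as ``c s^gamma``, and direct reproductive investment as
``b s^beta``.  With the mass--length power law ``s = h l^k`` the system
reduces to a single body-length equation

    dl = q (1 - r_t) l^lambda dt,

where ``q = (h^(alpha-1)/k)(a - c)``, ``lambda = k(alpha - 1) + 1`` and
``r_t = dg/dm`` is the instantaneous relative fecundity investment, the
fraction of the total-mass increment routed to reproduction (0 at birth,
rising with age).  This module houses both representations, the conversions
between them, and fixed-step RK4 forward simulators for each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MassParams",
    "LengthScale",
    "GrowthParams",
    "AllocationSchedule",
    "MassTrajectory",
    "LengthTrajectory",
    "lambda_from_alpha",
    "alpha_from_lambda",
    "simulate_length",
    "simulate_mass",
    "relative_fecundity_rate",
    "maintenance_fraction",
    "mass_length_convert",
]

DEFAULT_STEP = 0.05  # day; RK4 integration step


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MassParams:
    """Parameters of the somatic/gonadic mass system.

    a, alpha : energy-acquisition multiplier and exponent
    b, beta  : gonadic-investment multiplier and exponent
    c, gamma : non-growth-cost multiplier and exponent
    """

    a: float
    alpha: float
    b: float
    beta: float
    c: float
    gamma: float

    def __post_init__(self) -> None:
        _check_finite(a=self.a, alpha=self.alpha, b=self.b, beta=self.beta,
                      c=self.c, gamma=self.gamma)
        if self.a <= 0:
            raise ValueError("acquisition multiplier a must be > 0")
        if self.b < 0:
            raise ValueError("gonadic multiplier b must be >= 0")
        if self.c < 0:
            raise ValueError("cost multiplier c must be >= 0")

    def net_somatic_rate(self, s: float) -> float:
        """ds/dt = a s^alpha - c s^gamma - b s^beta at somatic mass ``s``."""
        return (self.a * s ** self.alpha - self.c * s ** self.gamma
                - self.b * s ** self.beta)

    def gonadic_rate(self, s: float) -> float:
        """dg/dt = b s^beta at somatic mass ``s``."""
        return self.b * s ** self.beta


@dataclass(frozen=True)
class LengthScale:
    """Mass--length power law ``s = h l^k``; cubic (k=3) by default."""

    h: float
    k: float = 3.0

    def __post_init__(self) -> None:
        _check_finite(h=self.h, k=self.k)
        if self.h <= 0 or self.k <= 0:
            raise ValueError("LengthScale requires h > 0 and k > 0")


@dataclass(frozen=True)
class GrowthParams:
    """Reduced body-length model parameters (q, lambda)."""

    q: float
    lam: float

    def __post_init__(self) -> None:
        _check_finite(q=self.q, lam=self.lam)
        if self.q <= 0:
            raise ValueError("growth scalar q must be > 0")


@dataclass(frozen=True)
class AllocationSchedule:
    """Time-varying relative fecundity investment r_t on a time grid.

    Linear interpolation between knots; the last value is held beyond the
    final knot.  r(0) = 0: no reproductive allocation at birth.
    """

    times: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "r", r)
        if times.ndim != 1 or times.shape != r.shape or times.size == 0:
            raise ValueError("times and r must be matching 1-d arrays")
        if times[0] != 0.0:
            raise ValueError("allocation schedule must start at t = 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("schedule times must be strictly increasing")
        if r[0] != 0.0:
            raise ValueError("r(0) must be 0 (no allocation at birth)")
        if np.any(r < 0) or np.any(r >= 1):
            raise ValueError("r_t must lie in [0, 1)")

    def __call__(self, t):
        return np.interp(t, self.times, self.r)


@dataclass(frozen=True)
class MassTrajectory:
    """Simulated (s, g, m) paths.

    Brood times appear twice in ``times``: once with the pre-brood gonadic
    mass (the brood's investment) and once, immediately after, with g reset
    to zero.
    """

    times: np.ndarray
    somatic: np.ndarray
    gonadic: np.ndarray
    brood_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def total(self) -> np.ndarray:
        return self.somatic + self.gonadic


@dataclass(frozen=True)
class LengthTrajectory:
    times: np.ndarray
    lengths: np.ndarray

    def length_at(self, t):
        """Linearly interpolated length at time(s) ``t``."""
        return np.interp(t, self.times, self.lengths)


def lambda_from_alpha(alpha: float, k: float = 3.0) -> float:
    """Length-scale exponent implied by the mass exponent: k(alpha-1)+1."""
    _check_finite(alpha=alpha, k=k)
    if k <= 0:
        raise ValueError("mass-length exponent k must be > 0")
    return k * (alpha - 1.0) + 1.0


def alpha_from_lambda(lam: float, k: float = 3.0) -> float:
    """Mass exponent implied by the length exponent: 1 + (lambda-1)/k."""
    _check_finite(lam=lam, k=k)
    if k <= 0:
        raise ValueError("mass-length exponent k must be > 0")
    return 1.0 + (lam - 1.0) / k


def mass_length_convert(scale: LengthScale, value: float,
                        direction: str = "to_length") -> float:
    """Convert via ``s = h l^k``.

    direction="to_length" maps somatic mass to length; "to_mass" the reverse.
    """
    value_arr = np.asarray(value, dtype=float)
    if np.any(value_arr <= 0):
        raise ValueError("mass/length values must be positive")
    if direction == "to_length":
        out = (value_arr / scale.h) ** (1.0 / scale.k)
    elif direction == "to_mass":
        out = scale.h * value_arr ** scale.k
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def maintenance_fraction(params: MassParams, s: float) -> float:
    """p_t = (c/a) s^(gamma-alpha): share of acquired energy spent off-growth.

    Constant (= c/a) when gamma == alpha, i.e. when non-growth costs are
    proportional to intake.
    """
    if s <= 0:
        raise ValueError("somatic mass must be positive")
    return (params.c / params.a) * s ** (params.gamma - params.alpha)


def relative_fecundity_rate(params: MassParams, s: float) -> float:
    """r = dg/dm = b s^(beta-alpha) / (a (1 - p)) with p = (c/a)s^(gamma-alpha).

    Raises if the total-mass increment is non-positive (denominator <= 0) or
    if the implied r falls outside [0, 1): the model admits no shrinkage and
    no super-unit reproductive allocation.
    """
    if s <= 0:
        raise ValueError("somatic mass must be positive")
    denom = params.a * (1.0 - maintenance_fraction(params, s))
    if denom <= 0:
        raise ValueError("dm_t <= 0: acquisition does not cover non-growth costs")
    r = params.b * s ** (params.beta - params.alpha) / denom
    if not 0.0 <= r < 1.0:
        raise ValueError(f"relative fecundity rate {r:.6g} outside [0, 1)")
    return r


def _resolve_r(schedule, times: np.ndarray) -> np.ndarray:
    """Evaluate an AllocationSchedule or arbitrary callable r(t) on a grid."""
    r = np.asarray(schedule(times), dtype=float)
    r = np.broadcast_to(r, times.shape).astype(float)
    if np.any(r >= 1.0):
        raise ValueError("r_t >= 1 on the integration grid: negative growth "
                         "is not admitted by the model")
    if np.any(r < 0.0):
        raise ValueError("r_t < 0 on the integration grid")
    return r


def _rk4_length(q: float, lam: float, r_half: np.ndarray, l0, h: float,
                n_steps: int) -> np.ndarray:
    """RK4 for dl = q(1-r(t)) l^lam dt with r pre-evaluated at half-steps.

    ``r_half`` has 2*n_steps + 1 entries (t_0, t_0+h/2, ..., t_end); ``l0``
    may be a scalar or a vector of initial lengths sharing the schedule.
    Returns an array of shape (n_steps+1,) or (n_steps+1, len(l0)).
    """
    l0 = np.asarray(l0, dtype=float)
    out = np.empty((n_steps + 1,) + l0.shape)
    out[0] = l = l0.copy()
    for i in range(n_steps):
        ra, rb, rc = r_half[2 * i], r_half[2 * i + 1], r_half[2 * i + 2]
        k1 = q * (1.0 - ra) * l ** lam
        k2 = q * (1.0 - rb) * (l + 0.5 * h * k1) ** lam
        k3 = q * (1.0 - rb) * (l + 0.5 * h * k2) ** lam
        k4 = q * (1.0 - rc) * (l + h * k3) ** lam
        l = l + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = l
    return out


def simulate_length(params: GrowthParams, schedule, l0: float, t_end: float,
                    step: float = DEFAULT_STEP) -> LengthTrajectory:
    """Forward-simulate dl = q(1-r_t) l^lambda dt by fixed-step RK4.

    Parameters
    ----------
    schedule : AllocationSchedule or callable t -> r
        Evaluated on the grid; an AllocationSchedule interpolates linearly
        between knots and holds its last value beyond them.
    l0 : initial body length (mm), > 0.
    step : maximum grid spacing (day); the grid divides [0, t_end] evenly.
    """
    if l0 <= 0:
        raise ValueError("initial length must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = max(1, int(math.ceil(t_end / step - 1e-12)))
    h = t_end / n
    times = np.linspace(0.0, t_end, n + 1)
    half_times = np.linspace(0.0, t_end, 2 * n + 1)
    r_half = _resolve_r(schedule, half_times)
    lengths = _rk4_length(params.q, params.lam, r_half, l0, h, n)
    return LengthTrajectory(times=times, lengths=lengths)


def simulate_mass(params: MassParams, s0: float, brood_times, t_end: float,
                  step: float = DEFAULT_STEP) -> MassTrajectory:
    """Integrate the somatic/gonadic system with gonadic resets at broods.

    ds = (a s^alpha - c s^gamma - b s^beta) dt and dg = b s^beta dt between
    brood times; g starts at zero and is set to zero immediately after each
    brood time (the pre-brood value is the brood's gonadic investment).
    """
    if s0 <= 0:
        raise ValueError("initial somatic mass must be positive")
    if params.net_somatic_rate(s0) <= 0:
        raise ValueError("ds/dt <= 0 at s0: the model does not describe shrinkage")
    brood_times = np.sort(np.asarray(brood_times, dtype=float))
    if brood_times.size and (brood_times[0] <= 0 or brood_times[-1] > t_end):
        raise ValueError("brood times must lie in (0, t_end]")

    events = np.concatenate([[0.0], brood_times, [t_end]])
    events = np.unique(events)

    times_out: list[np.ndarray] = []
    s_out: list[np.ndarray] = []
    g_out: list[np.ndarray] = []
    s, g = s0, 0.0
    for t_lo, t_hi in zip(events[:-1], events[1:]):
        span = t_hi - t_lo
        n = max(1, int(math.ceil(span / step - 1e-12)))
        h = span / n
        seg_t = np.linspace(t_lo, t_hi, n + 1)
        seg_s = np.empty(n + 1)
        seg_g = np.empty(n + 1)
        seg_s[0], seg_g[0] = s, g
        for i in range(n):
            ks1 = params.net_somatic_rate(s)
            if ks1 <= 0:
                raise ValueError("somatic growth rate became non-positive; "
                                 "shrinkage is outside the model")
            kg1 = params.gonadic_rate(s)
            s2 = s + 0.5 * h * ks1
            ks2, kg2 = params.net_somatic_rate(s2), params.gonadic_rate(s2)
            s3 = s + 0.5 * h * ks2
            ks3, kg3 = params.net_somatic_rate(s3), params.gonadic_rate(s3)
            s4 = s + h * ks3
            ks4, kg4 = params.net_somatic_rate(s4), params.gonadic_rate(s4)
            s = s + (h / 6.0) * (ks1 + 2 * ks2 + 2 * ks3 + ks4)
            g = g + (h / 6.0) * (kg1 + 2 * kg2 + 2 * kg3 + kg4)
            seg_s[i + 1], seg_g[i + 1] = s, g
        times_out.append(seg_t)
        s_out.append(seg_s)
        g_out.append(seg_g)
        if t_hi in brood_times:
            # right-continuous reset; the next segment's first grid point
            # repeats t_hi with g = 0, so both limits appear in the output
            g = 0.0

    return MassTrajectory(times=np.concatenate(times_out),
                          somatic=np.concatenate(s_out),
                          gonadic=np.concatenate(g_out),
                          brood_times=brood_times)
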
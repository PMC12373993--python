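"""Forward model: ODE simulators, conversions and their closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from allogrowth.growth_model import (AllocationSchedule, GrowthParams,
                                     LengthScale, MassParams,
                                     alpha_from_lambda, lambda_from_alpha,
                                     maintenance_fraction,
                                     mass_length_convert,
                                     relative_fecundity_rate, simulate_length,
                                     simulate_mass)


class TestExponentConversions:
    @pytest.mark.parametrize("alpha,k,lam", [
        (2 / 3, 3, 0.0),        # von Bertalanffy exponent, cubic scaling
        (1.0, 3, 1.0),          # identity growth
        (2.178 / 3, 3, 0.178),  # near the fitted Daphnia exponent
    ])
    def test_lambda_from_alpha(self, alpha, k, lam):
        assert lambda_from_alpha(alpha, k) == pytest.approx(lam, abs=1e-12)

    def test_fitted_exponent_pair(self):
        # the fitted length exponent 0.179 maps to a mass exponent of 0.726
        # under cubic mass-length scaling, close to the classic 2/3
        assert alpha_from_lambda(0.179, 3) == pytest.approx(0.726, abs=5e-4)
        assert alpha_from_lambda(1.0, 5.7) == pytest.approx(1.0)
        assert alpha_from_lambda(0.0, 3) == pytest.approx(2 / 3)

    @given(alpha=st.floats(-2, 2), k=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, alpha, k):
        assert alpha_from_lambda(lambda_from_alpha(alpha, k), k) == \
            pytest.approx(alpha, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lambda_from_alpha(float("nan"), 3)
        with pytest.raises(ValueError):
            lambda_from_alpha(0.7, 0.0)
        with pytest.raises(ValueError):
            alpha_from_lambda(0.2, 0.0)


def bernoulli_length(l0, q, lam, t):
    """Closed-form solution of dl = q l^lam dt (no reproduction)."""
    t = np.asarray(t, dtype=float)
    if lam == 1:
        return l0 * np.exp(q * t)
    return (l0 ** (1 - lam) + (1 - lam) * q * t) ** (1 / (1 - lam))


class TestSimulateLength:
    @pytest.mark.parametrize("lam", [-0.5, 0.0, 0.179, 0.5, 1.0])
    def test_closed_form_no_allocation(self, lam):
        q, l0, t_end = 0.2, 0.8, 10.0
        traj = simulate_length(GrowthParams(q=q, lam=lam), lambda t: 0.0,
                               l0, t_end, step=0.1)
        expected = bernoulli_length(l0, q, lam, traj.times)
        assert np.max(np.abs(traj.lengths / expected - 1)) < 1e-8

    def test_rk4_convergence_order(self):
        p = GrowthParams(q=0.2, lam=0.3)
        exact = bernoulli_length(0.8, 0.2, 0.3, 10.0)
        errs = [abs(simulate_length(p, lambda t: 0.0, 0.8, 10.0,
                                    step=h).lengths[-1] - exact)
                for h in (0.4, 0.2)]
        assert errs[1] < errs[0] / 8  # at least cubic decay on halving

    def test_schedule_interpolation_and_monotonicity(self):
        sched = AllocationSchedule(times=np.array([0.0, 5.0, 20.0]),
                                   r=np.array([0.0, 0.5, 0.9]))
        traj = simulate_length(GrowthParams(q=0.17, lam=0.18), sched,
                               0.8, 40.0, step=0.05)
        assert np.all(np.diff(traj.lengths) >= 0)
        assert traj.lengths[0] == 0.8
        # holds the last r value beyond the final knot: slow but positive
        late = np.diff(traj.lengths[-20:])
        assert np.all(late > 0)

    def test_rejects_r_at_or_above_one(self):
        with pytest.raises(ValueError, match="negative growth"):
            simulate_length(GrowthParams(q=0.2, lam=0.2), lambda t: 1.0,
                            0.8, 5.0)

    def test_rejects_bad_initials(self):
        with pytest.raises(ValueError):
            simulate_length(GrowthParams(q=0.2, lam=0.2), lambda t: 0.0,
                            -1.0, 5.0)

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="start at t = 0"):
            AllocationSchedule(times=np.array([1.0, 2.0]),
                               r=np.array([0.0, 0.1]))
        with pytest.raises(ValueError, match=r"r\(0\)"):
            AllocationSchedule(times=np.array([0.0, 2.0]),
                               r=np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            AllocationSchedule(times=np.array([0.0, 2.0]),
                               r=np.array([0.0, 1.0]))


class TestSimulateMass:
    params = MassParams(a=1.0, alpha=0.7, b=0.12, beta=0.75, c=0.3, gamma=0.8)

    def test_conservation_and_resets(self):
        traj = simulate_mass(self.params, s0=0.1,
                             brood_times=[5.0, 10.0, 15.0], t_end=20.0,
                             step=0.02)
        assert np.allclose(traj.total, traj.somatic + traj.gonadic)
        assert traj.gonadic[0] == 0.0
        for tb in traj.brood_times:
            after = np.nonzero(traj.times == tb)[0]
            assert traj.gonadic[after[-1]] == 0.0   # reset copy of the time
            assert traj.gonadic[after[0]] > 0.0     # pre-brood investment
        moved = np.diff(traj.times) > 0  # brood times appear twice
        assert np.all(np.diff(traj.somatic)[moved] > 0)

    def test_b_zero_reduces_to_von_bertalanffy_putter(self):
        p = MassParams(a=1.0, alpha=2 / 3, b=0.0, beta=1.0, c=0.2, gamma=1.0)
        traj = simulate_mass(p, s0=0.05, brood_times=[], t_end=30.0, step=0.02)
        assert np.all(traj.gonadic == 0.0)
        ref = solve_ivp(lambda t, s: p.a * s ** p.alpha - p.c * s ** p.gamma,
                        (0, 30.0), [0.05], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        assert np.max(np.abs(traj.somatic / ref.sol(traj.times)[0] - 1)) < 1e-7

    def test_equal_exponents_constant_allocation_ratio(self):
        p = MassParams(a=1.0, alpha=0.7, b=0.1, beta=0.7, c=0.3, gamma=0.7)
        traj = simulate_mass(p, s0=0.1, brood_times=[], t_end=20.0, step=0.01)
        dg = np.diff(traj.gonadic)
        dm = np.diff(traj.total)
        assert np.max(np.abs(dg / dm - p.b / (p.a - p.c))) < 1e-10

    def test_shrinkage_rejected(self):
        bad = MassParams(a=0.2, alpha=0.7, b=0.0, beta=1.0, c=1.0, gamma=0.7)
        with pytest.raises(ValueError, match="shrinkage"):
            simulate_mass(bad, s0=1.0, brood_times=[], t_end=5.0)

    def test_brood_times_outside_range_rejected(self):
        with pytest.raises(ValueError, match="brood times"):
            simulate_mass(self.params, s0=0.1, brood_times=[25.0], t_end=20.0)

    def test_mass_length_equivalence(self):
        # with alpha = gamma the somatic path converted through s = h l^k
        # must solve the reduced length equation with q = (h^(alpha-1)/k)(a-c)
        # and lambda = k(alpha-1)+1, with r_t taken along the mass path
        p = MassParams(a=1.0, alpha=0.7, b=0.15, beta=0.75, c=0.3, gamma=0.7)
        scale = LengthScale(h=0.05, k=3.0)
        t_end, step = 30.0, 0.005
        mass = simulate_mass(p, s0=0.1, brood_times=[], t_end=t_end, step=step)
        s_of_t = lambda t: np.interp(t, mass.times, mass.somatic)
        r_of_t = np.vectorize(
            lambda t: relative_fecundity_rate(p, float(s_of_t(t))))
        q = scale.h ** (p.alpha - 1) / scale.k * (p.a - p.c)
        lam = lambda_from_alpha(p.alpha, scale.k)
        l0 = mass_length_convert(scale, 0.1, "to_length")
        length = simulate_length(GrowthParams(q=q, lam=lam), r_of_t, l0,
                                 t_end, step=step)
        implied = mass_length_convert(scale, s_of_t(length.times), "to_length")
        assert np.max(np.abs(length.lengths / implied - 1)) < 1e-6


class TestRates:
    def test_relative_rate_exponents_cancel(self):
        p = MassParams(a=1.0, alpha=0.7, b=0.1, beta=0.7, c=0.3, gamma=0.7)
        for s in (0.01, 1.0, 50.0):
            assert relative_fecundity_rate(p, s) == pytest.approx(
                0.1 / 0.7, rel=1e-12)

    def test_relative_rate_zero_when_b_zero(self):
        p = MassParams(a=1.0, alpha=0.7, b=0.0, beta=0.9, c=0.2, gamma=0.8)
        assert relative_fecundity_rate(p, 2.0) == 0.0

    def test_relative_rate_finite_difference_oracle(self):
        p = MassParams(a=1.0, alpha=0.68, b=0.12, beta=0.8, c=0.25,
                       gamma=0.75)
        s0 = 0.5
        traj = simulate_mass(p, s0=s0, brood_times=[], t_end=1e-2, step=1e-4)
        dg = np.diff(traj.gonadic)
        dm = np.diff(traj.total)
        assert dg[0] / dm[0] == pytest.approx(
            relative_fecundity_rate(p, s0), rel=1e-3)

    def test_relative_rate_errors(self):
        starving = MassParams(a=1.0, alpha=0.7, b=0.1, beta=0.7, c=2.0,
                              gamma=0.7)
        with pytest.raises(ValueError, match="dm_t"):
            relative_fecundity_rate(starving, 1.0)
        greedy = MassParams(a=1.0, alpha=0.7, b=0.9, beta=0.7, c=0.3,
                            gamma=0.7)
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            relative_fecundity_rate(greedy, 1.0)

    def test_maintenance_fraction(self):
        p = MassParams(a=1.0, alpha=0.7, b=0.0, beta=1.0, c=0.3, gamma=0.7)
        assert maintenance_fraction(p, 123.0) == pytest.approx(0.3)
        p0 = MassParams(a=1.0, alpha=0.7, b=0.0, beta=1.0, c=0.0, gamma=1.0)
        assert maintenance_fraction(p0, 5.0) == 0.0
        p1 = MassParams(a=1.0, alpha=0.7, b=0.0, beta=1.0, c=0.2, gamma=0.8)
        assert maintenance_fraction(p1, math.exp(10)) == pytest.approx(
            0.2 * math.e, rel=1e-12)


class TestMassLengthConvert:
    def test_examples(self):
        assert mass_length_convert(LengthScale(h=1, k=3), 2.0,
                                   "to_mass") == pytest.approx(8.0)
        assert mass_length_convert(LengthScale(h=0.05, k=3), 0.4,
                                   "to_length") == pytest.approx(2.0)

    @given(value=st.floats(1e-6, 1e6), h=st.floats(1e-3, 1e3),
           k=st.floats(0.5, 5))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, value, h, k):
        scale = LengthScale(h=h, k=k)
        back = mass_length_convert(
            scale, mass_length_convert(scale, value, "to_mass"), "to_length")
        assert back == pytest.approx(value, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mass_length_convert(LengthScale(h=1, k=3), 0.0, "to_mass")
        with pytest.raises(ValueError, match="direction"):
            mass_length_convert(LengthScale(h=1, k=3), 1.0, "sideways")
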
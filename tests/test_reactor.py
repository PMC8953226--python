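"""Chemostat simulation, regime classification and lifeline statistics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sretools import (
    FeedSchedule,
    KineticParams,
    Lifeline,
    ReactorParams,
    classify_regime,
    minimum_glucose,
    regime_residence,
    semilog_slope,
    simulate_chemostat,
)
from sretools.reactor import GLUCOSE_MOLAR_MASS


def default_init(kinetics, D=None, params=None):
    params = params or ReactorParams()
    if D is None:   # the exact continuous-feed operating point of the rig
        D = params.base_feed_rate / 1000.0 * 60.0 / params.working_volume
    cs = kinetics.steady_state_glucose(D)
    x = kinetics.yield_xs * (params.feed_glucose - cs * GLUCOSE_MOLAR_MASS * 1e-6)
    return cs, x


class TestParameters:
    def test_continuous_feed_dilution_is_one_tenth_per_hour(self):
        # 2.83 mL/min into 1.7 L -> D = 0.0999 1/h
        p = ReactorParams()
        D = p.base_feed_rate / 1000.0 * 60.0 / p.working_volume
        assert D == pytest.approx(0.1, abs=5e-4)

    @pytest.mark.parametrize("field,value", [
        ("working_volume", 0.0), ("feed_glucose", -1.0), ("base_feed_rate", 0.0),
    ])
    def test_reactor_params_must_be_positive(self, field, value):
        with pytest.raises(ValueError):
            ReactorParams(**{field: value})

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            FeedSchedule(mode="intermittent", cycle_period=2.0, off_duration=2.0)
        with pytest.raises(ValueError):
            FeedSchedule(mode="intermittent", on_rate=0.0)
        with pytest.raises(ValueError):
            KineticParams(starvation_threshold=300.0)

    def test_intermittent_cycle_starts_with_feed_off(self):
        s = FeedSchedule(mode="intermittent")
        assert s.flow_rate(30.0, 2.83) == 0.0
        assert s.flow_rate(150.0, 2.83) == 3.64


class TestSimulate:
    def test_steady_state_matches_closed_form_monod(self):
        """Long continuous-feed run converges to K_M*q_req/(q_max - q_req)."""
        k = KineticParams(q_max=2.0, K_M=100.0, yield_xs=0.5)
        # independent closed form: q_req = D/(Y*M)
        D = 0.1
        q_req = D / (0.5 * GLUCOSE_MOLAR_MASS / 1000.0)
        cs_star = 100.0 * q_req / (2.0 - q_req)
        assert k.steady_state_glucose(D) == pytest.approx(cs_star, rel=1e-12)
        assert cs_star == pytest.approx(124.75, abs=0.01)

        p = ReactorParams(base_feed_rate=D * 1.7 * 1000.0 / 60.0)
        x_star = 0.5 * (p.feed_glucose - cs_star * GLUCOSE_MOLAR_MASS * 1e-6)
        traj = simulate_chemostat(p, FeedSchedule(mode="continuous"), k,
                                  init=(cs_star * 1.5, x_star), duration=20.0, dt=1.0)
        assert traj.glucose[-1] == pytest.approx(cs_star, rel=5e-3)

    def test_no_uptake_no_feed_keeps_glucose_constant(self):
        k = KineticParams(q_max=1e-12, K_M=100.0, yield_xs=0.5)
        sched = FeedSchedule(mode="intermittent", cycle_period=60.0,
                             off_duration=30.0, on_rate=2.83)
        traj = simulate_chemostat(ReactorParams(), sched, k, init=(100.0, 10.0),
                                  duration=0.25, dt=1.0, frozen_biomass=True)
        assert np.allclose(traj.glucose, 100.0, rtol=1e-9)

    def test_misaligned_schedule_and_bad_inputs_raise(self):
        k = KineticParams()
        p = ReactorParams()
        sched = FeedSchedule(mode="intermittent")
        with pytest.raises(ValueError):
            simulate_chemostat(p, sched, k, init=(100.0, 10.0), duration=0.1, dt=0.0)
        with pytest.raises(ValueError):
            simulate_chemostat(p, sched, k, init=(-1.0, 10.0), duration=0.1, dt=1.0)
        with pytest.raises(ValueError, match="align"):
            simulate_chemostat(p, sched, k, init=(100.0, 10.0), duration=0.1, dt=7.0)

    def test_glucose_carbon_balance_closes(self):
        """Feed glucose = effluent + yield-implied consumption + accumulation."""
        k = KineticParams()
        p = ReactorParams()
        cs0, x0 = default_init(k)
        traj = simulate_chemostat(p, FeedSchedule(mode="continuous"), k,
                                  init=(cs0 * 2, x0 * 0.9), duration=5.0, dt=1.0)
        V, dt = p.working_volume, 1.0
        flow = p.base_feed_rate / 1000.0 / 60.0
        glc_g = traj.glucose * GLUCOSE_MOLAR_MASS * 1e-6
        fed = flow * p.feed_glucose * dt * (len(traj.time) - 1)
        out = np.sum(flow * glc_g[:-1] * dt)
        consumed = (traj.biomass[-1] * V - traj.biomass[0] * V
                    + np.sum(flow * traj.biomass[:-1] * dt)) / k.yield_xs
        acc = (glc_g[-1] - glc_g[0]) * V
        assert abs(fed - out - consumed - acc) / fed < 1e-3

    def test_frozen_biomass_changes_little_over_one_cycle(self):
        k = KineticParams()
        p = ReactorParams()
        cs0, x0 = default_init(k)
        sched = FeedSchedule(mode="intermittent")
        free = simulate_chemostat(p, sched, k, init=(cs0, x0), duration=0.15, dt=1.0)
        assert abs(free.biomass[-1] / free.biomass[0] - 1.0) < 3e-3


class TestRegimes:
    k = KineticParams()

    @pytest.mark.parametrize("glucose,expected", [
        (300.0, "overflow"),
        (30.0, "starvation"),
        (207.0, "limitation"),   # boundary belongs to limitation
        (53.0, "limitation"),
        (100.0, "limitation"),
    ])
    def test_classification(self, glucose, expected):
        assert classify_regime(glucose, self.k) == expected

    def test_negative_glucose_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(-1.0, self.k)

    def test_square_wave_residence_is_exact(self):
        t = np.arange(101.0)
        c = np.where(t < 58, 30.0, 100.0)   # 58 s of 100 s starved
        frac = regime_residence(Lifeline(time=t, glucose=c), self.k)
        assert frac["starvation"] == pytest.approx(0.58, abs=1e-12)
        assert frac["limitation"] == pytest.approx(0.42, abs=1e-12)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_is_pure_limitation(self):
        frac = regime_residence(Lifeline(time=np.arange(10.0),
                                         glucose=np.full(10, 100.0)), self.k)
        assert frac["limitation"] == 1.0

    def test_simulated_cycle_fractions_match_ode_oracle(self):
        """Residence fractions agree with an adaptive-step ODE integration."""
        p = ReactorParams()
        sched = FeedSchedule(mode="intermittent")
        cs0, x0 = default_init(self.k)
        traj = simulate_chemostat(p, sched, self.k, init=(cs0, x0),
                                  duration=0.45, dt=1.0)
        frac = regime_residence(traj.lifeline(), self.k)

        kin = self.k
        feed_umol = p.feed_glucose / GLUCOSE_MOLAR_MASS * 1e6

        def rhs(t, y, flow):
            cs, x = y
            din = flow / 1000.0 / 60.0 / p.working_volume
            qs = kin.q_max * 1000.0 / 3600.0 * cs / (kin.K_M + cs)
            mu = kin.yield_xs * qs * GLUCOSE_MOLAR_MASS * 1e-6
            return [din * (feed_umol - cs) - qs * x, (mu - din) * x]

        y, segs, t0 = [cs0, x0], [], 0.0
        for _ in range(3):
            for flow, dur in ((0.0, 120.0), (3.64, 420.0)):
                sol = solve_ivp(rhs, (t0, t0 + dur), y, args=(flow,),
                                dense_output=True, rtol=1e-10, atol=1e-10)
                segs.append(sol)
                y, t0 = sol.y[:, -1], t0 + dur
        tt = np.linspace(0.0, t0, 100001)
        cs = np.concatenate([
            s.sol(tt[(tt >= s.t[0]) & (tt <= s.t[-1])])[0] for s in segs[:1]
        ] + [s.sol(tt[(tt > s.t[0]) & (tt <= s.t[-1])])[0] for s in segs[1:]])
        starved = np.mean(cs[:-1] < kin.starvation_threshold)
        assert frac["starvation"] == pytest.approx(starved, abs=2e-3)

    def test_fractions_monotone_in_starvation_threshold(self):
        p = ReactorParams()
        sched = FeedSchedule(mode="intermittent")
        cs0, x0 = default_init(self.k)
        traj = simulate_chemostat(p, sched, self.k, init=(cs0, x0),
                                  duration=0.3, dt=1.0)
        fracs = []
        for thr in (20.0, 53.0, 90.0, 130.0):
            kk = KineticParams(starvation_threshold=thr)
            fracs.append(regime_residence(traj.lifeline(), kk)["starvation"])
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestSlope:
    def test_exact_exponential_recovered_exactly(self):
        t = np.arange(0.0, 120.0)
        c = 150.0 * np.exp(-0.02 * t)
        fit = semilog_slope(Lifeline(time=t, glucose=c), (0.0, 119.0))
        assert fit.slope_per_s == pytest.approx(0.02, rel=1e-12)
        assert fit.slope_per_min == pytest.approx(1.2, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_exponential_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 120.0)
        c = 150.0 * np.exp(-0.02 * t) * (1.0 + 0.02 * rng.standard_normal(t.size))
        fit = semilog_slope(Lifeline(time=t, glucose=c), (0.0, 119.0))
        assert fit.slope_per_s == pytest.approx(0.02, rel=0.1)

    def test_constant_trace_has_zero_slope(self):
        t = np.arange(0.0, 10.0)
        fit = semilog_slope(Lifeline(time=t, glucose=np.full(10, 80.0)), (0.0, 9.0))
        assert fit.slope_per_s == pytest.approx(0.0, abs=1e-15)

    def test_deep_limitation_slope_equals_first_order_constant(self):
        """With Cs << K_M the depletion constant is q_max*X/K_M (volumetric)."""
        k = KineticParams()
        X = 11.1
        sched = FeedSchedule(mode="intermittent", cycle_period=30.0,
                             off_duration=10.0, on_rate=2.83)
        traj = simulate_chemostat(ReactorParams(), sched, k, init=(100.0, X),
                                  duration=10.0 / 60.0, dt=0.5, frozen_biomass=True)
        fit = semilog_slope(traj.lifeline(), (120.0, 360.0))
        k_theory = k.q_max * 1000.0 / 3600.0 * X / k.K_M
        assert fit.slope_per_s == pytest.approx(k_theory, rel=0.05)

    def test_window_validation(self):
        t = np.arange(0.0, 10.0)
        line = Lifeline(time=t, glucose=np.linspace(10.0, 1.0, 10))
        with pytest.raises(ValueError):
            semilog_slope(line, (0.0, 1.0))     # < 3 points
        zero = Lifeline(time=t, glucose=np.zeros(10))
        with pytest.raises(ValueError):
            semilog_slope(zero, (0.0, 9.0))


class TestMinimumGlucose:
    def test_monotone_decay_minimum_is_last_value(self):
        t = np.arange(0.0, 50.0)
        c = 100.0 * np.exp(-0.05 * t)
        cmin, tmin = minimum_glucose(Lifeline(time=t, glucose=c))
        assert cmin == c[-1] and tmin == t[-1]

    def test_reduced_uptake_raises_feed_off_minimum(self):
        """At 60% of nominal kinetics the 2-min trough is shallower."""
        k = KineticParams()
        p = ReactorParams()
        sched = FeedSchedule(mode="intermittent", cycle_period=9.0,
                             off_duration=2.0, on_rate=3.64)
        mins = {}
        for scale in (1.0, 0.6):
            traj = simulate_chemostat(p, sched, k, init=(150.0, 11.1),
                                      duration=0.15, dt=1.0, uptake_scale=scale)
            mins[scale], _ = minimum_glucose(traj, (0.0, 120.0))
        assert mins[0.6] > mins[1.0]
        assert mins[0.6] < 150.0

    def test_steady_state_minimum_is_steady_value(self):
        k = KineticParams()
        cs0, x0 = default_init(k)
        traj = simulate_chemostat(ReactorParams(), FeedSchedule(mode="continuous"),
                                  k, init=(cs0, x0), duration=0.2, dt=1.0)
        cmin, _ = minimum_glucose(traj)
        assert cmin == pytest.approx(cs0, rel=1e-6)

    def test_empty_window_rejected(self):
        t = np.arange(0.0, 10.0)
        line = Lifeline(time=t, glucose=np.full(10, 5.0))
        with pytest.raises(ValueError):
            minimum_glucose(line, (100.0, 200.0))
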
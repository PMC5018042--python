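"""Closed-form limits, cure thresholds, envelopes and the periodic limit."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from immunopulse import (
    LinearPeriodicForcing,
    NondimParameters,
    SolverSettings,
    TreatmentSchedule,
    V_infinity,
    c_infinity,
    cure_conditions_single_boost,
    g_max,
    linear_periodic_limit,
    min_curative_dose,
    p_bar,
    periodic_envelopes,
    simulate,
    single_boost_limits,
)
from immunopulse.asymptotics import single_boost_d_m
from immunopulse.scenarios import draw_nondim_parameters


def params(**overrides) -> NondimParameters:
    base = dict(k_v=1.0, k_m=0.8, k_CR=1.2, mu_D=0.9, mu_R=1.1, mu_C=0.7,
                k=1.0, g=0.4, a=1.0, V_p=0.0)
    base.update(overrides)
    return NondimParameters(**base)


class TestSingleBoostLimits:
    def test_no_endogenous_antigen_means_all_limits_vanish(self):
        lim = single_boost_limits(params(V_p=0.0))
        assert lim.c_infinity == 0.0
        assert (lim.d_m_limit, lim.d_c_limit, lim.d_r_limit, lim.r_limit) == (0,) * 4
        assert lim.p_bar is None

    def test_unit_parameters_give_half_ctl_level(self, unit_params):
        assert c_infinity(unit_params) == pytest.approx(0.5)
        lim = single_boost_limits(unit_params)
        assert (lim.d_m_limit, lim.d_c_limit, lim.d_r_limit, lim.r_limit) == (1.0,) * 4

    def test_cascade_limits_follow_rate_ladder(self):
        q = params(V_p=0.6, k_m=2.0, k_CR=0.5, mu_D=4.0, mu_R=0.25)
        lim = single_boost_limits(q)
        assert lim.d_m_limit == pytest.approx(0.3)
        assert lim.d_c_limit == pytest.approx(0.6)
        assert lim.d_r_limit == pytest.approx(0.15)
        assert lim.r_limit == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulation_converges_to_closed_form_limits(self, seed):
        rng = np.random.default_rng(seed)
        q = draw_nondim_parameters(rng, V_p=float(rng.uniform(0.2, 2.0)))
        horizon = 50.0 / q.min_rate
        x0 = np.array([1.0, 0, 0, 0, 0, 0, 0])
        traj = simulate(q, TreatmentSchedule.empty(), x0,
                        SolverSettings(rtol=1e-10, atol=1e-13, horizon=horizon))
        lim = single_boost_limits(q)
        expected = [lim.d_m_limit, lim.d_c_limit, lim.d_r_limit, lim.r_limit, lim.c_infinity]
        final = traj.final_state[1:6]
        np.testing.assert_allclose(final, expected, rtol=1e-3)

    def test_mature_dc_transient_closed_form(self):
        q = params(k_v=1.0, k_m=0.8, V_p=0.3)
        x0 = np.array([2.0, 0, 0, 0, 0, 0, 0])
        traj = simulate(q, TreatmentSchedule.empty(), x0,
                        SolverSettings(rtol=1e-11, atol=1e-14, horizon=10.0))
        np.testing.assert_allclose(
            traj.component("d_m"), single_boost_d_m(traj.t, 2.0, q), rtol=1e-7, atol=1e-10
        )


class TestTumourThreshold:
    def test_threshold_is_scaled_ctl_excess(self):
        q = params(V_p=3.0, a=2.0, g=0.1)
        assert p_bar(q) == pytest.approx(2.0 * c_infinity(q) / 0.1 - 1.0)

    def test_boundary_equilibrium_reported_absent(self):
        q = params(V_p=1.0)
        g_match = q.a * c_infinity(q)  # places p_bar exactly at zero
        assert p_bar(params(V_p=1.0, g=g_match)) is None

    def test_threshold_separates_extinction_from_escape(self):
        """Single-boost simulations from below/above p_bar reach opposite
        fates (immune cascade started at its V_p-driven steady state)."""
        from immunopulse.scenarios import _immune_steady_state

        q = params(V_p=3.0, a=2.0, g=0.2)
        pb = p_bar(q)
        assert pb is not None and pb > 0.2
        for frac, expected in ((0.5, "extinction"), (2.0, "escape")):
            x0 = _immune_steady_state(q)
            x0[0] = 0.05  # small vaccine boost on top of the steady state
            x0[6] = frac * pb
            traj = simulate(q, TreatmentSchedule.empty(), x0,
                            SolverSettings(horizon=2000.0))
            assert traj.status == expected


class TestCureConditions:
    def test_unit_parameters_sit_on_the_infeasible_boundary(self, unit_params):
        verdict = cure_conditions_single_boost(unit_params)
        assert verdict.g_max == pytest.approx(1.0)
        assert not verdict.feasible
        assert verdict.V_p_required == math.inf

    def test_feasibility_needs_antigen_above_bound(self):
        q = params(a=2.0, mu_D=1.0, mu_R=1.0, k=1.0, g=1.0, mu_C=0.7, k_CR=1.2, k_m=0.8)
        verdict = cure_conditions_single_boost(q)
        assert verdict.g_max == pytest.approx(2.0)
        expected_bound = 1.0 * 0.8 * 0.7 * 1.0 * 1.0 * 1.2 / (1.0 * (2.0 - 1.0))
        assert verdict.V_p_required == pytest.approx(expected_bound)
        assert not verdict.feasible  # V_p = 0
        q_hi = params(**{**q.__dict__, "V_p": 2 * expected_bound})
        assert cure_conditions_single_boost(q_hi).feasible

    def test_without_endogenous_antigen_cure_is_impossible(self, rng):
        for _ in range(20):
            q = draw_nondim_parameters(rng, V_p=0.0)
            assert not cure_conditions_single_boost(q).feasible


class TestPeriodicEnvelopes:
    def test_vanishing_dose_closes_all_envelopes(self):
        env = periodic_envelopes(params(), 1e-12, 1.0)
        assert env.V_M < 1e-11 and env.c_max < 1e-10
        assert env.p_bar_min is None

    def test_stale_dose_limit(self):
        # k_v * delta_t large: lower envelope empties, upper tends to V0
        env = periodic_envelopes(params(k_v=5.0), 2.0, 10.0)
        assert env.V_m == pytest.approx(0.0, abs=1e-20)
        assert env.V_M == pytest.approx(2.0, rel=1e-12)

    def test_envelope_ordering(self, rng):
        for _ in range(20):
            q = draw_nondim_parameters(rng)
            env = periodic_envelopes(q, float(rng.uniform(0.1, 5.0)), float(rng.uniform(0.3, 2.0)))
            assert 0 < env.V_m < env.V_M
            assert env.c_min < env.c_max
            if env.p_bar_min is not None and env.p_bar_max is not None:
                assert env.p_bar_min <= env.p_bar_max

    @pytest.mark.parametrize("seed", range(10))
    def test_limiting_ctl_level_lies_inside_band(self, seed):
        """After burn-in the simulated CTL level must sit inside the
        closed-form envelope band [c_min, c_max]."""
        rng = np.random.default_rng(seed)
        q = draw_nondim_parameters(rng)
        V0 = float(rng.uniform(0.2, 3.0))
        env = periodic_envelopes(q, V0, 1.0)
        burn_in = max(120.0, 10.0 / q.min_rate)
        traj = simulate(
            q, TreatmentSchedule.periodic(V0, 1.0, int(burn_in) + 1), np.zeros(7),
            SolverSettings(horizon=burn_in, rtol=1e-9, atol=1e-12, sample_dt=0.05),
        )
        late = traj.t > burn_in - 5.0
        c = traj.component("c")[late]
        assert np.all(c >= env.c_min * (1 - 1e-6) - 1e-12)
        assert np.all(c <= env.c_max * (1 + 1e-6) + 1e-12)

    def test_c_min_monotone_in_dose_and_interval(self):
        q = params()
        doses = np.linspace(0.5, 5.0, 9)
        c_by_dose = [periodic_envelopes(q, V0, 1.0).c_min for V0 in doses]
        assert np.all(np.diff(c_by_dose) > 0)
        intervals = np.linspace(0.3, 3.0, 9)
        c_by_dt = [periodic_envelopes(q, 1.0, dt).c_min for dt in intervals]
        assert np.all(np.diff(c_by_dt) < 0)


class TestMinimalCurativeDose:
    def test_continuous_dosing_limit_needs_vanishing_dose(self):
        q = params(g=0.1)
        doses = [min_curative_dose(q, dt).dose for dt in (1.0, 0.1, 0.01, 0.001)]
        assert all(d is not None for d in doses)
        assert np.all(np.diff(doses) < 0)
        assert doses[-1] < 1e-2 * doses[0]

    def test_growth_above_effective_ceiling_is_infeasible(self):
        q = params()
        design = min_curative_dose(q, 1.0)
        gm_eff = g_max(q) * math.exp(-q.k_v)
        assert design.g_max_effective == pytest.approx(gm_eff)
        q_hot = params(g=1.01 * gm_eff)
        hot = min_curative_dose(q_hot, 1.0)
        assert not hot.feasible and hot.dose is None

    def test_feasible_region_recovers_single_boost_ceiling_as_interval_shrinks(self):
        q = params()
        eff = [min_curative_dose(q, dt).g_max_effective for dt in (2.0, 1.0, 0.1, 1e-4)]
        assert np.all(np.diff(eff) > 0)
        assert eff[-1] == pytest.approx(g_max(q), rel=1e-3)

    def test_margined_dose_cures_and_underdose_fails(self):
        """Dosing 1.2x the minimal curative dose from half the guaranteed
        basin reaches the extinction floor; a 10x underdose started above
        the failure threshold escapes."""
        from immunopulse.scenarios import _in_band_state

        q = params(g=0.3, a=2.0)
        design = min_curative_dose(q, 1.0)
        assert design.feasible

        dose = 1.2 * design.dose
        env = periodic_envelopes(q, dose, 1.0)
        assert env.p_bar_min is not None
        x0 = _in_band_state(env, dose * math.exp(-q.k_v) / (1 - math.exp(-q.k_v)))
        x0[6] = 0.5 * env.p_bar_min
        horizon = 1500.0
        traj = simulate(q, TreatmentSchedule.periodic(dose, 1.0, int(horizon) + 1),
                        x0, SolverSettings(horizon=horizon))
        assert traj.status == "extinction"

        low = 0.1 * design.dose
        env_low = periodic_envelopes(q, low, 1.0)
        p0 = 1.0 if env_low.p_bar_max is None else 2.0 * env_low.p_bar_max + 1.0
        x0 = _in_band_state(env_low, low * math.exp(-q.k_v) / (1 - math.exp(-q.k_v)))
        x0[6] = p0
        traj = simulate(q, TreatmentSchedule.periodic(low, 1.0, int(horizon) + 1),
                        x0, SolverSettings(horizon=horizon))
        assert traj.status == "escape"


class TestLinearPeriodicLimit:
    def test_constant_coefficients_reduce_to_fixed_point(self):
        forcing = LinearPeriodicForcing(lambda t: 1.4, lambda t: 0.7)
        for t in (0.0, 0.37, 0.99, 3.2):
            assert linear_periodic_limit(forcing, t) == pytest.approx(2.0, rel=1e-9)

    def test_matches_printed_mature_dc_limit(self):
        """Forcing with the limiting vaccine envelope and constant decay k_m
        reproduces the two-exponential periodic mature-DC profile."""
        k_v, k_m, V0 = 1.0, 1.3, 2.0
        forcing = LinearPeriodicForcing(lambda t: V_infinity(t, V0, 1.0, k_v), lambda t: k_m)

        def reference(t):
            tau = t - math.floor(t)
            return (
                V0 / ((1 - math.exp(-k_v)) * (1 - math.exp(-k_m)))
                * ((1 - math.exp(-k_m)) * math.exp(-k_v * tau)
                   - (1 - math.exp(-k_v)) * math.exp(-k_m * tau))
                / (k_m - k_v)
            )

        for t in (0.0, 0.25, 0.5, 0.77, 0.999, 4.6):
            assert linear_periodic_limit(forcing, t) == pytest.approx(reference(t), rel=1e-9)

    def test_transients_decay_at_mean_rate_per_period(self):
        F = lambda t: 1.0 + 0.5 * math.sin(2 * math.pi * t)
        G = lambda t: 0.8 + 0.3 * math.cos(2 * math.pi * t)
        forcing = LinearPeriodicForcing(F, G)
        sol = solve_ivp(lambda t, y: [F(t) - G(t) * y[0]], (0.0, 12.0), [0.0],
                        rtol=1e-11, atol=1e-13, dense_output=True)
        gaps = [abs(float(sol.sol(n)[0]) - linear_periodic_limit(forcing, n)) for n in range(4, 12)]
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        np.testing.assert_allclose(ratios, math.exp(-forcing.G_A), rtol=1e-4)

    def test_limit_is_periodic_and_satisfies_the_ode(self):
        F = lambda t: 1.0 + 0.5 * math.sin(2 * math.pi * t)
        G = lambda t: 0.8 + 0.3 * math.cos(2 * math.pi * t)
        forcing = LinearPeriodicForcing(F, G)
        h = 1e-6
        for t in (0.1, 0.4, 0.85):
            x_star = linear_periodic_limit(forcing, t)
            assert x_star == pytest.approx(linear_periodic_limit(forcing, t + 1.0), rel=1e-9)
            deriv = (linear_periodic_limit(forcing, t + h) - linear_periodic_limit(forcing, t - h)) / (2 * h)
            assert abs(deriv - (F(t) - G(t) * x_star)) < 1e-4

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LinearPeriodicForcing(lambda t: 1.0, lambda t: -0.1)
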
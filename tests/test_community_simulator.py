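"""Community dynamics: kinetic identities, integrator oracles, steady
states, competition and conservation."""

from dataclasses import replace

import numpy as np
import pytest

from nobsim.community_simulator import (
    DEFAULT_CONFIG,
    CommunityState,
    SimulationConfig,
    carbon_fixation_rate,
    closed_form_steady_state,
    growth_limitation,
    integrate,
    run_to_steady_state,
    steady_state_growth_rate,
    substrate_oxidation_rate,
)
from nobsim.soil_environment import EnvironmentState
from nobsim.trait_catalog import FunctionalTypeSet, evaluate_k_m_o2

from .conftest import make_profile


class TestOxidationRate:
    def test_zero_at_zero_substrate_o2_or_biomass(self, typeset):
        p = typeset["Nitrospira"]
        assert substrate_oxidation_rate(p, 0.0, 1e-3, 1e-6) == 0.0
        assert substrate_oxidation_rate(p, 1e-3, 0.0, 1e-6) == 0.0
        assert substrate_oxidation_rate(p, 1e-3, 1e-3, 0.0) == 0.0

    def test_half_saturation_identity(self):
        """At s = K_m and saturating O2 the rate is V_max*B/2."""
        p = make_profile(k_m_no2=100.0, k_m_o2=1e-3)
        s = 100.0 * 1e-6  # K_m in M
        o2 = 1.0  # 1e6 uM >> K_m_o2
        b = 1e-6
        expected = p.v_max_no2 * b / 2
        assert substrate_oxidation_rate(p, s, o2, b) == pytest.approx(
            expected, rel=1e-6
        )

    def test_matches_direct_formula_on_random_inputs(self, typeset):
        """Independent spreadsheet-style evaluation of the dual-Monod
        product, to 1e-12 relative."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = typeset.profiles[rng.integers(3)]
            s, o2, b = 10 ** rng.uniform(-7, -2, 3)
            k_o2 = evaluate_k_m_o2(p, o2)
            expected = (
                p.v_max_no2
                * (s * 1e6 / (p.k_m_no2 + s * 1e6))
                * (o2 * 1e6 / (k_o2 + o2 * 1e6))
                * b
            )
            assert substrate_oxidation_rate(p, s, o2, b) == pytest.approx(
                expected, rel=1e-12
            )

    def test_oc_oxidation_only_for_mixotroph(self, typeset):
        spira = typeset["Nitrospira"]
        mixo = typeset["Nitrobacter_mixo"]
        assert substrate_oxidation_rate(spira, 1e-3, 1e-3, 1e-6, "oc") == 0.0
        assert substrate_oxidation_rate(mixo, 1e-3, 1e-3, 1e-6, "oc") > 0.0


class TestCarbonFixation:
    def test_zero_without_energy_or_carbon(self, typeset):
        p = typeset["Nitrospira"]
        assert carbon_fixation_rate(p, 0.0, 1e-6, 1.0) == 0.0
        assert carbon_fixation_rate(p, 1e-4, 1e-6, 0.0) == 0.0

    def test_half_saturation_identity(self, typeset):
        """At [C] = K_m_c the rate is half the energy-limited maximum."""
        p = typeset["Nitrospira"]
        energy = 1e-3
        c = p.k_m_c * 1e-6
        full = p.growth_yield * energy
        assert carbon_fixation_rate(p, c, 1e-6, energy) == pytest.approx(
            full / 2, rel=1e-9
        )


class TestGrowthLimitation:
    def _state(self, qc, qn):
        return CommunityState(
            biomass_c=np.array([1e-6]),
            quota_c=np.array([qc]),
            quota_n=np.array([qn]),
        )

    def test_zero_at_minimum_quota(self):
        cfg = DEFAULT_CONFIG
        assert growth_limitation(self._state(cfg.q_min_c, 10.0), 0) == 0.0

    def test_saturates_at_one_for_large_quotas(self):
        assert growth_limitation(self._state(1e6, 1e6), 0) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_min_rule(self):
        cfg = DEFAULT_CONFIG
        # C Droop term 0.5, N Droop term 0.8
        state = self._state(2 * cfg.q_min_c, 5 * cfg.q_min_n)
        assert growth_limitation(state, 0) == pytest.approx(0.5)


class TestIntegrate:
    def test_exponential_growth_at_mu_max_without_mortality(self):
        """With saturating substrate, replete quotas and no crowding, net
        growth approaches mu_max; over five doublings the trajectory is
        exponential within 1%."""
        # uptake capacity ~1e4x growth demand so quota limitation is
        # negligible; effectively no mortality
        p = make_profile(
            mortality=1e-12, v_max_no2=2e11 * 1e-5, v_max_c=2e11 * 1e-5
        )
        ts = FunctionalTypeSet((p,))
        env = EnvironmentState(no2=1e-2, oc=0.0, o2=1.0, co2=1e-2)
        cfg = replace(
            DEFAULT_CONFIG,
            b_cap=None,
            seed_quota_factor=100.0,
            n_assimilation_fraction=0.5,
        )
        horizon = 5 * np.log(2) / p.mu_max
        traj = integrate(ts, env, horizon=horizon, config=cfg)
        growth = traj.biomass_c[-1, 0] / traj.biomass_c[0, 0]
        mu_eff = np.log(growth) / horizon
        assert mu_eff == pytest.approx(p.mu_max, rel=0.01)

    def test_zero_seed_is_absorbing(self, typeset, rich_env):
        init = CommunityState(
            biomass_c=np.zeros(3),
            quota_c=np.full(3, 2.0),
            quota_n=np.full(3, 0.3),
        )
        traj = integrate(typeset, rich_env, initial=init, horizon=1e7)
        assert np.all(traj.biomass_c == 0)

    def test_agrees_with_explicit_euler_oracle(self, typeset, rich_env):
        """Brute-force small-step explicit Euler reproduces the adaptive
        solver trajectory endpoint to 1e-4 relative."""
        from nobsim.community_simulator import _pack_initial, _rhs_factory

        cfg = DEFAULT_CONFIG
        horizon = 2e6
        traj = integrate(typeset, rich_env, horizon=horizon, config=cfg)
        y = _pack_initial(CommunityState.initial(3, cfg), rich_env, cfg)
        rhs = _rhs_factory(typeset.profiles, rich_env, cfg)
        n_steps = 40000
        dt = horizon / n_steps
        t = 0.0
        for _ in range(n_steps):
            y = y + dt * rhs(t, y)
            t += dt
        # atol floor covers types driven to the brink of extinction,
        # where both integrators agree only in absolute terms
        np.testing.assert_allclose(
            traj.biomass_c[-1], y[:3], rtol=1e-4, atol=1e-12
        )

    def test_nonpositive_horizon_rejected(self, typeset, rich_env):
        with pytest.raises(ValueError):
            integrate(typeset, rich_env, horizon=0.0)


class TestNonNegativity:
    def test_random_parameter_draws_stay_nonnegative(self):
        """State variables remain >= 0 across random trait draws and
        environments."""
        rng = np.random.default_rng(11)
        for i in range(60):
            p = make_profile(
                name=f"p{i}",
                mu_max=10 ** rng.uniform(-6.5, -4.5),
                k_m_no2=10 ** rng.uniform(0.5, 3),
                v_max_no2=10 ** rng.uniform(2, 5),
                growth_yield=rng.uniform(0.01, 0.3),
                mortality=10 ** rng.uniform(-7.5, -6),
                k_m_o2=10 ** rng.uniform(0.5, 4),
            )
            env = EnvironmentState(
                no2=10 ** rng.uniform(-6, -2),
                oc=0.0,
                o2=10 ** rng.uniform(-4, -2),
            )
            traj = integrate(
                FunctionalTypeSet((p,)), env, horizon=10 ** rng.uniform(5, 7.5)
            )
            assert np.all(traj.biomass_c >= 0)
            assert np.all(traj.quota_c > 0)
            assert np.all(traj.quota_n > 0)


class TestRunToSteadyState:
    def test_washout_when_growth_below_mortality(self):
        """A type whose achievable growth rate is below its mortality
        goes extinct."""
        p = make_profile(mu_max=5e-7, mortality=3e-7, k_m_no2=5000.0)
        env = EnvironmentState(no2=1e-6, oc=0.0, o2=1e-3)
        assert steady_state_growth_rate(p, env) < p.mortality
        res = run_to_steady_state(FunctionalTypeSet((p,)), env)
        assert res.converged
        assert res.biomass[0] == 0.0

    def test_survivor_growth_balances_mortality(self, single_type, rich_env):
        """Flux balance: at steady state the survivor's growth rate
        equals its realized (crowding-inflated) mortality, and biomass
        matches the closed-form break-even B* = B_cap(mu/D - 1)."""
        res = run_to_steady_state(single_type, rich_env)
        assert res.converged
        p = single_type.profiles[0]
        cfg = DEFAULT_CONFIG
        mu = res.fluxes.growth_rate[0]
        realized_mortality = p.mortality * (
            1 + res.biomass.sum() / cfg.b_cap
        )
        assert mu == pytest.approx(realized_mortality, rel=1e-6)
        mu_ss = steady_state_growth_rate(p, rich_env)
        b_star = cfg.b_cap * (mu_ss / p.mortality - 1)
        assert res.biomass[0] == pytest.approx(b_star, rel=1e-3)

    def test_matches_closed_form_on_regression_suite(self, typeset):
        """Ten fixed environments: ODE steady state equals the analytic
        solution within 0.1% on surviving biomass."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            env = EnvironmentState(
                no2=10 ** rng.uniform(-5.1, -2),
                oc=float(rng.uniform(0, 5e-3)),
                o2=10 ** rng.uniform(-4, -2),
            )
            res = run_to_steady_state(typeset, env)
            b_cf, _ = closed_form_steady_state(typeset, env)
            assert res.converged
            np.testing.assert_allclose(
                res.biomass, b_cf, rtol=1e-3, atol=1e-11
            )

    def test_deterministic(self, typeset, rich_env):
        r1 = run_to_steady_state(typeset, rich_env)
        r2 = run_to_steady_state(typeset, rich_env)
        np.testing.assert_array_equal(r1.biomass, r2.biomass)


class TestCompetition:
    def test_two_type_contest_follows_break_even_ordering(self):
        """In chemostat (drawdown) mode the winner of a two-type contest
        for nitrite is the type with the lower analytic break-even
        concentration S* = D K / (mu_max - D); 20 random contests here,
        the full 100-contest sweep runs in the acceptance suite."""
        from .test_acceptance import run_rstar_contests

        wins, total = run_rstar_contests(n_contests=20, seed=123)
        assert wins == total


class TestBatchConservation:
    def test_nitrogen_ledger_closes(self, typeset):
        """Closed-batch bookkeeping: pool depletion equals cumulative
        oxidation, and assimilated N equals biomass N gain plus
        mortality N losses, to 1e-6 relative."""
        cfg = replace(DEFAULT_CONFIG, mode="batch", b_cap=None)
        env = EnvironmentState(no2=1e-4, oc=2e-3, o2=1e-3)
        traj = integrate(typeset, env, horizon=5e6, config=cfg, n_out=8)
        no2_t, _, cum_ox, cum_assim, cum_mort = traj.extras[-1]
        consumed = env.no2 - no2_t
        assert consumed == pytest.approx(cum_ox, rel=1e-6)
        bio_n0 = (traj.biomass_c[0] * traj.quota_n[0]).sum()
        bio_n = (traj.biomass_c[-1] * traj.quota_n[-1]).sum()
        assert cum_assim == pytest.approx(
            (bio_n - bio_n0) + cum_mort, rel=1e-6
        )
        # assimilation is the configured fraction of oxidation
        assert cum_assim == pytest.approx(
            cfg.n_assimilation_fraction * cum_ox, rel=1e-9
        )
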
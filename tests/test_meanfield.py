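"""Tests for the stationary mean-field theory against closed forms and sims."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import excitnet as en


class TestSteadyConductance:
    def test_zero_rate(self, params):
        assert en.steady_conductance(3.0, 0.0, params) == 0.0

    def test_direct_product(self, params):
        assert en.steady_conductance(2.0, 0.1, params) == pytest.approx(1.0)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            en.steady_conductance(-1.0, 0.1, params)

    def test_matches_time_averaged_simulated_conductance(self, params):
        # drifting state: theory g* = tau_ex K r_bar vs simulated <g_i(t)>
        cc = en.CouplingConfig(N=100, K_mean=2.0, Delta_K=1.2)
        K = en.make_coupling(cc)
        sol = en.solve_self_consistent(K, params)
        sim = en.SimulationConfig(duration=7000, seed=8, record_V=True,
                                  record_stride=10)
        res = en.simulate(params, cc, sim)
        settled = res.t_trace >= 2000.0
        g_avg = res.g_trace[settled].mean(axis=0)
        for i in (10, 50, 90):
            assert g_avg[i] == pytest.approx(sol.g_star[i], rel=0.02)


class TestTimeToThreshold:
    def test_zero_drive_never_fires(self, params):
        assert en.time_to_threshold(0.0, 0.0, params) == np.inf

    def test_boundary_drive_diverges(self, params):
        bound = en.drive_threshold(params)
        assert bound == pytest.approx((1 / 5.0) * (10.0 / 50.0))
        assert en.time_to_threshold(1.0, bound, params) == np.inf
        # just above the bound: finite but large
        t = en.time_to_threshold(1.0, bound * 1.001, params)
        assert np.isfinite(t) and t > 100.0

    def test_closed_form_vs_ode_oracle_grid(self, params):
        # 100-point (K, r_bar) grid: integrate the constant-conductance
        # membrane equation with tight tolerances and compare t*
        rng = np.random.default_rng(12)
        bound = en.drive_threshold(params)
        checked = 0
        while checked < 100:
            K = rng.uniform(0.3, 12.0)
            r = rng.uniform(0.01, 0.2)
            if K * r <= bound * 1.02:
                continue
            g = params.tau_ex * K * r
            t_star = en.time_to_threshold(K, r, params)

            def rhs(t, V):
                return ((params.V_rest - V) + g * (params.E_ex - V)) / params.tau

            def hit(t, V):
                return V[0] - params.V_theta

            hit.terminal = True
            hit.direction = 1
            ode = solve_ivp(rhs, [0.0, 10 * t_star + 10], [params.V_rest],
                            events=hit, rtol=1e-12, atol=1e-12)
            assert ode.t_events[0][0] == pytest.approx(t_star, rel=1e-8)
            checked += 1

    def test_monotone_decreasing_in_drive(self, params):
        drives = np.linspace(0.05, 2.0, 200)
        t = np.array([en.time_to_threshold(1.0, d, params) for d in drives])
        finite = np.isfinite(t)
        assert np.all(np.diff(t[finite]) < 0)


class TestSMFMap:
    def test_silent_network_self_consistent(self, params):
        assert en.smf_map(0.0, np.array([1.0, 2.0, 3.0]), params) == 0.0

    def test_bounded_by_refractory_ceiling(self, params):
        K = en.make_coupling(en.CouplingConfig(N=50, K_mean=5, Delta_K=2))
        big = en.smf_map(1e6, K, params)
        assert big < 1.0 / params.t_ref
        assert big == pytest.approx(1.0 / params.t_ref, rel=1e-3)

    def test_nondecreasing(self, params):
        K = en.make_coupling(en.CouplingConfig(N=30, K_mean=2, Delta_K=1.5))
        rs = np.linspace(0, 0.2, 300)
        vals = [en.smf_map(r, K, params) for r in rs]
        assert np.all(np.diff(vals) >= -1e-15)


class TestSolveSelfConsistent:
    def test_low_coupling_inactive(self, params):
        K = en.make_coupling(en.CouplingConfig(N=100, K_mean=0.1, Delta_K=0.0))
        sol = en.solve_self_consistent(K, params)
        assert sol.r_bar == 0.0
        assert np.all(sol.rate_hz == 0)

    def test_fixed_point_residual(self, params):
        K = en.make_coupling(en.CouplingConfig(N=100, K_mean=2.0, Delta_K=1.8))
        sol = en.solve_self_consistent(K, params)
        assert sol.r_bar > 0
        assert abs(en.smf_map(sol.r_bar, K, params) - sol.r_bar) < 1e-9
        assert sol.residual < 1e-9

    def test_r_bar_is_mean_rate_including_silent(self, params):
        K = en.make_coupling(en.CouplingConfig(N=100, K_mean=2.0, Delta_K=1.8))
        sol = en.solve_self_consistent(K, params)
        assert sol.silent.sum() > 0  # partially inactive state
        assert np.mean(sol.rate_hz) == pytest.approx(sol.r_bar_hz, rel=1e-9)

    def test_g_star_identity(self, params):
        K = en.make_coupling(en.CouplingConfig(N=20, K_mean=3.0, Delta_K=0.5))
        sol = en.solve_self_consistent(K, params)
        assert np.allclose(sol.g_star, params.tau_ex * K * sol.r_bar)

    def test_continuum_limit_matches_large_N(self, params):
        sol_N = en.solve_self_consistent(
            en.make_coupling(en.CouplingConfig(N=2000, K_mean=2.0, Delta_K=1.2)),
            params)
        sol_c = en.solve_self_consistent_continuum(2.0, 1.2, params)
        assert sol_c.r_bar == pytest.approx(sol_N.r_bar, rel=1e-3)

    def test_rate_discrepancy_shrinks_with_N(self, params):
        # fully drifting state: SMF becomes exact in the thermodynamic limit
        devs = {}
        for N, seed in ((50, 3), (100, 3), (200, 3)):
            cc = en.CouplingConfig(N=N, K_mean=3.0, Delta_K=1.8)
            K = en.make_coupling(cc)
            sol = en.solve_self_consistent(K, params)
            res = en.simulate(params, cc, en.SimulationConfig(duration=12000,
                                                              seed=seed))
            prof = en.rates_from_spikes(res.spikes)
            devs[N] = np.mean(np.abs(prof.rate_hz - sol.rate_hz) / sol.rate_hz)
        assert devs[200] < devs[50]
        assert devs[200] < 0.02


class TestPhaseBoundaries:
    def test_zero_spread_boundaries_coincide(self, params):
        df = en.phase_boundaries([0.0], params, N=50)
        row = df.iloc[0]
        assert row.K_inactive == pytest.approx(row.K_all_active, abs=1e-3)

    def test_partially_inactive_anchor_lies_between_curves(self, params):
        df = en.phase_boundaries([1.8], params, N=100)
        row = df.iloc[0]
        assert row.K_inactive < 2.0 < row.K_all_active

    def test_boundary_agrees_with_simulation_scan(self, params):
        # at Delta_K = 1.2, scan K_mean for the first fully active profile
        df = en.phase_boundaries([1.2], params, N=100)
        K_all = df.iloc[0].K_all_active
        grid = np.arange(np.floor(K_all * 4) / 4 - 0.5, K_all + 0.6, 0.25)
        silent_frac = []
        for Kb in grid:
            if Kb <= 1.2:
                silent_frac.append(1.0)
                continue
            cc = en.CouplingConfig(N=100, K_mean=float(Kb), Delta_K=1.2)
            res = en.simulate(params, cc,
                              en.SimulationConfig(duration=7000, seed=4))
            prof = en.rates_from_spikes(res.spikes, 2000, 5000)
            silent_frac.append(np.mean(prof.rate_hz < 1.0))
        silent_frac = np.array(silent_frac)
        crossings = grid[np.nonzero(silent_frac == 0)[0]]
        assert len(crossings) > 0
        # simulated all-active onset within one grid cell of the analytic curve
        assert abs(crossings[0] - K_all) <= 0.26
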
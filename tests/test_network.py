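"""Unit and property tests for the COBA network simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import excitnet as en
from excitnet.params import ConfigError


class TestCoupling:
    def test_equidistant_endpoints_and_midpoint(self):
        K = en.make_coupling(en.CouplingConfig(N=3, K_mean=2, Delta_K=1))
        assert np.allclose(K, [1.0, 2.0, 3.0])

    def test_equidistant_spacing(self):
        K = en.make_coupling(en.CouplingConfig(N=100, K_mean=2.0, Delta_K=0.4))
        assert K[0] == pytest.approx(1.6)
        assert K[-1] == pytest.approx(2.4)
        assert np.allclose(np.diff(K), 0.8 / 99)

    def test_zero_spread_degenerate(self):
        for scheme in ("equidistant", "flat_random"):
            K = en.make_coupling(en.CouplingConfig(N=2, K_mean=5, Delta_K=0,
                                                   scheme=scheme, seed=0))
            assert np.allclose(K, [5.0, 5.0])

    def test_flat_random_range_and_mean(self):
        cfg = en.CouplingConfig(N=5000, K_mean=2.0, Delta_K=0.5,
                                scheme="flat_random", seed=1)
        K = en.make_coupling(cfg)
        assert K.min() >= 1.5 and K.max() <= 2.5
        assert np.mean(K) == pytest.approx(2.0, abs=0.02)
        assert np.all(np.diff(K) >= 0)  # sorted: index doubles as rank

    def test_negative_coupling_rejected(self):
        with pytest.raises(ConfigError):
            en.CouplingConfig(N=10, K_mean=2.0, Delta_K=2.5)


class TestWeights:
    def test_uniform_matrix(self):
        w = en.make_weights(4, 0.0)
        assert np.all(np.diag(w.w) == 0)
        off = w.w[~np.eye(4, dtype=bool)]
        assert np.all(off == 1.0)

    def test_jitter_range_and_mean(self):
        w = en.make_weights(100, 0.5, seed=3)
        off = w.w[~np.eye(100, dtype=bool)]
        assert off.min() >= 0.5 and off.max() <= 1.5
        # row sums approach (N-1) on average
        assert np.mean(w.w.sum(axis=1) / 99) == pytest.approx(1.0, abs=0.02)
        assert np.all(np.diag(w.w) == 0)

    def test_distinct_seeds_distinct_matrices(self):
        w1 = en.make_weights(50, 0.5, seed=1)
        w2 = en.make_weights(50, 0.5, seed=2)
        assert not np.array_equal(w1.w, w2.w)
        assert abs(w1.w.mean() - w2.w.mean()) < 0.02

    def test_jitter_width_one_rejected(self):
        with pytest.raises(ConfigError):
            en.make_weights(10, 1.0)

    def test_renormalize(self):
        w = en.make_weights(30, 0.5, seed=0, renormalize=True)
        assert np.allclose(w.w.sum(axis=1) / 29, 1.0)


class TestStep:
    def test_rest_is_fixed_point(self, params):
        st = en.NetworkState(t=0.0, V=np.full(2, params.V_rest),
                             g=np.zeros(2), y_steps=np.zeros(2, np.int64),
                             ref_remaining=np.zeros(2))
        sim = en.SimulationConfig(dt=0.01)
        for _ in range(50):
            st, spiked = en.step(st, params, np.array([1.0, 1.0]), None, sim)
            assert len(spiked) == 0
        assert np.allclose(st.V, params.V_rest)

    def test_spike_increments_peer_conductance(self, params):
        # neuron 0 just above threshold -> spikes on the first step;
        # neuron 1 receives Delta g = K_1 * 1/(N-1) = K_1 at that step
        st = en.NetworkState(t=0.0,
                             V=np.array([params.V_theta + 0.1, params.V_rest]),
                             g=np.zeros(2), y_steps=np.zeros(2, np.int64),
                             ref_remaining=np.zeros(2))
        sim = en.SimulationConfig(dt=0.01)
        K = np.array([2.0, 3.0])
        st, spiked = en.step(st, params, K, None, sim)
        assert list(spiked) == [0]
        assert st.g[1] == pytest.approx(K[1])
        assert st.g[0] == 0.0  # no self-coupling
        assert st.V[0] == params.V_rest
        assert st.ref_remaining[0] == params.t_ref

    def test_refractory_clamp_and_countdown(self, params):
        st = en.NetworkState(t=0.0, V=np.array([params.V_rest, -55.0]),
                             g=np.array([5.0, 0.0]),
                             y_steps=np.zeros(2, np.int64),
                             ref_remaining=np.array([3.0, 0.0]))
        sim = en.SimulationConfig(dt=0.01)
        st, _ = en.step(st, params, np.zeros(2), None, sim)
        assert st.V[0] == params.V_rest          # clamped despite large g
        assert st.ref_remaining[0] == pytest.approx(2.99)

    def test_conductance_decays_during_refractoriness(self, params):
        st = en.NetworkState(t=0.0, V=np.full(2, params.V_rest),
                             g=np.array([1.0, 1.0]),
                             y_steps=np.zeros(2, np.int64),
                             ref_remaining=np.array([3.0, 0.0]))
        sim = en.SimulationConfig(dt=0.01)
        st, _ = en.step(st, params, np.zeros(2), None, sim)
        assert st.g[0] == pytest.approx(np.exp(-0.01 / params.tau_ex))


class TestSimulate:
    def test_low_coupling_dies_out(self, params, anchor_records):
        record = anchor_records[(0.1, 0.0)]
        assert len(record.window(2000.0, record.duration)) == 0

    def test_determinism(self, params):
        cc = en.CouplingConfig(N=50, K_mean=3.0, Delta_K=1.0)
        sim = en.SimulationConfig(duration=2000, seed=42)
        r1 = en.simulate(params, cc, sim).spikes
        r2 = en.simulate(params, cc, sim).spikes
        assert np.array_equal(r1.time, r2.time)
        assert np.array_equal(r1.neuron, r2.neuron)
        r3 = en.simulate(params, cc, sim.replace(seed=43)).spikes
        assert not np.array_equal(r1.time, r3.time)

    def test_continuation_matches_single_run(self, params):
        cc = en.CouplingConfig(N=30, K_mean=3.0, Delta_K=1.0)
        full = en.simulate(params, cc, en.SimulationConfig(duration=1000, seed=9))
        head = en.simulate(params, cc, en.SimulationConfig(duration=400, seed=9))
        tail = en.simulate(params, cc, en.SimulationConfig(duration=600, seed=9),
                           state=head.final_state)
        merged_t = np.concatenate([head.spikes.time, tail.spikes.time])
        assert np.allclose(np.sort(full.spikes.time), np.sort(merged_t))
        assert np.allclose(full.final_state.V, tail.final_state.V)

    def test_isi_floor_at_refractory_period(self, params, anchor_records):
        record = anchor_records[(3.0, 0.1)]
        for i in range(0, 100, 17):
            isi = record.isis_of(i)
            if len(isi):
                assert isi.min() >= params.t_ref

    def test_rate_never_exceeds_refractory_ceiling(self, params, anchor_profiles):
        for profile in anchor_profiles.values():
            assert profile.rate_hz.max() <= 1000.0 / params.t_ref + 1e-9

    def test_exact_conductance_decay_between_increments(self, params):
        # subthreshold network (g below the drive bound, tiny K): no spikes,
        # so g must decay exactly exponentially the whole run
        st = en.NetworkState(t=0.0, V=np.full(5, params.V_rest),
                             g=np.linspace(0.01, 0.15, 5),
                             y_steps=np.zeros(5, np.int64),
                             ref_remaining=np.zeros(5))
        sim = en.SimulationConfig(duration=50, seed=0, record_V=True,
                                  record_stride=100)
        res = en.simulate(params, np.full(5, 0.01), sim, state=st)
        assert len(res.spikes) == 0
        g0 = res.g_trace[0]
        for k, t in enumerate(res.t_trace):
            expected = g0 * np.exp(-(t - res.t_trace[0]) / params.tau_ex)
            assert np.allclose(res.g_trace[k], expected, rtol=1e-12)

    def test_euler_error_scales_linearly_in_dt(self, params):
        # frozen conductance (huge tau_ex), single uncoupled pair:
        # compare the Euler endpoint against the closed-form linear-ODE
        # solution; halving dt by 10 must shrink the error ~10-fold
        frozen = params.replace(tau_ex=1e12, t_ref=0.0)
        g0 = 0.15  # subthreshold drive: V relaxes toward a fixed point
        errs = []
        for dt in (0.01, 0.001):
            st = en.NetworkState(t=0.0, V=np.full(2, params.V_rest),
                                 g=np.full(2, g0),
                                 y_steps=np.zeros(2, np.int64),
                                 ref_remaining=np.zeros(2))
            sim = en.SimulationConfig(dt=dt, duration=20.0)
            res = en.simulate(frozen, np.zeros(2), sim, state=st)
            A = (params.V_rest + g0 * params.E_ex) / params.tau
            B = (1.0 + g0) / params.tau
            V_exact = A / B + (params.V_rest - A / B) * np.exp(-B * 20.0)
            errs.append(abs(res.final_state.V[0] - V_exact))
        assert errs[0] / errs[1] == pytest.approx(10.0, rel=0.15)

    def test_blowup_reported_with_neuron_and_time(self, params):
        st = en.NetworkState(t=0.0, V=np.array([np.inf, -60.0]),
                             g=np.zeros(2), y_steps=np.zeros(2, np.int64),
                             ref_remaining=np.zeros(2))
        with pytest.raises(en.NumericalBlowupError, match="neuron 0"):
            en.simulate(params, np.ones(2), en.SimulationConfig(duration=1.0),
                        state=st)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(N=st.integers(3, 40), K_mean=st.floats(0.5, 10),
       ratio=st.floats(0.0, 0.99))
def test_coupling_mean_and_bounds_property(N, K_mean, ratio):
    cfg = en.CouplingConfig(N=N, K_mean=K_mean, Delta_K=ratio * K_mean)
    K = en.make_coupling(cfg)
    assert np.all(K >= 0)
    assert np.mean(K) == pytest.approx(K_mean, rel=1e-9)
    assert K.max() <= K_mean + ratio * K_mean + 1e-12
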
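"""Fixed-timestep simulator of the autonomous excitatory COBA network.

The network consists of N conductance-based leaky integrate-and-fire neurons
coupled all-to-all without self-coupling.  Each neuron i obeys

    tau dV_i/dt = (V_rest - V_i) + g_i (E_ex - V_i) + I_ext [+ noise],

with the conductance decaying as tau_ex dg_i/dt = -g_i between spikes and
jumping by Delta g_i = K_i/(N-1) * sum_{j != i} w_ij y_j whenever presynaptic
neurons spike.  A spike resets V to V_rest and clamps it there for the
refractory period t_ref, during which the membrane equation is suspended (the
conductance keeps decaying and keeps receiving synaptic increments).

Integration is forward Euler for V at fixed dt; the conductance decay is
applied with the exact factor exp(-dt/tau_ex) per step.  Threshold crossings
are detected after the V update of each step; the resulting conductance
increments are applied at the end of the same step and therefore first
influence the next step's membrane update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ConfigError, CouplingConfig, NeuronParameters, SimulationConfig
from .records import NetworkState, SpikeRecord


class NumericalBlowupError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""


@dataclass
class WeightMatrix:
    """Dense nonnegative synaptic weight matrix with zero diagonal.

    For ``jitter_width`` = 0 all off-diagonal entries equal 1 (the uniform
    mean-field matrix); otherwise entries are 1 + eta with eta drawn from a
    flat distribution of zero mean and half-width ``jitter_width``.
    """

    w: np.ndarray
    jitter_width: float = 0.0

    @property
    def N(self) -> int:
        return self.w.shape[0]

    @property
    def is_uniform(self) -> bool:
        return self.jitter_width == 0.0


def make_coupling(config: CouplingConfig) -> np.ndarray:
    """Per-neuron afferent coupling strengths K_i.

    The equidistant scheme returns
    ``K_i = K_mean - Delta_K + 2 Delta_K (i-1)/(N-1)`` for i = 1..N; the
    flat-random scheme draws N values uniformly from
    [K_mean - Delta_K, K_mean + Delta_K] and sorts them ascending so that
    neuron index doubles as coupling rank in both schemes.
    """
    N, Kb, dK = config.N, config.K_mean, config.Delta_K
    if config.scheme == "equidistant":
        return Kb - dK + 2.0 * dK * np.arange(N) / (N - 1)
    rng = np.random.default_rng(config.seed)
    return np.sort(rng.uniform(Kb - dK, Kb + dK, size=N))


def make_weights(N: int, jitter_width: float = 0.0,
                 seed: int | None = None,
                 renormalize: bool = False) -> WeightMatrix:
    """Synaptic weight matrix, optionally jittered.

    Off-diagonal entries are 1 + eta with eta ~ flat(-jitter_width,
    +jitter_width); the diagonal is zero (no self-coupling).  With
    ``renormalize`` each row is rescaled so that sum_j w_ij / (N-1) = 1
    exactly; by default rows are left as drawn (the jitter has zero mean, so
    normalization holds in expectation).
    """
    if not (0.0 <= jitter_width < 1.0):
        raise ConfigError(
            f"jitter_width must lie in [0, 1) to keep weights positive, got {jitter_width}"
        )
    if jitter_width == 0.0:
        w = np.ones((N, N))
    else:
        rng = np.random.default_rng(seed)
        w = 1.0 + rng.uniform(-jitter_width, jitter_width, size=(N, N))
    np.fill_diagonal(w, 0.0)
    if renormalize and jitter_width > 0.0:
        w *= (N - 1) / w.sum(axis=1, keepdims=True)
    return WeightMatrix(w, jitter_width)


@njit(cache=True)
def _run_kernel(V, g, y_steps, ref_remaining, K, w, uniform_w,
                dt, n_steps, tau, tau_ex, V_rest, V_theta, E_ex,
                t_ref, spike_width, I_ext, noise_sd, noise_seed,
                t0, spike_t, spike_i,
                V_trace, g_trace, record_stride):
    N = V.shape[0]
    decay = np.exp(-dt / tau_ex)
    cap = spike_t.shape[0]
    n_spk = 0
    use_noise = noise_sd > 0.0
    if use_noise:
        np.random.seed(noise_seed)
    noise_amp = noise_sd * np.sqrt(dt) / tau
    record = record_stride > 0
    rec_idx = 0
    for step in range(n_steps):
        # membrane update (suspended while refractory)
        for i in range(N):
            if ref_remaining[i] > 0.0:
                ref_remaining[i] -= dt
                if ref_remaining[i] < 0.0:
                    ref_remaining[i] = 0.0
                V[i] = V_rest
            else:
                dv = (dt / tau) * ((V_rest - V[i]) + g[i] * (E_ex - V[i]) + I_ext)
                if use_noise:
                    dv += noise_amp * np.random.normal()
                V[i] += dv
                if not np.isfinite(V[i]):
                    return n_spk, step, i
        # exact exponential conductance decay
        for i in range(N):
            g[i] *= decay
        # threshold crossings: spike, reset, refractory onset
        t_now = t0 + (step + 1) * dt
        any_active = False
        for i in range(N):
            if y_steps[i] > 0:
                any_active = True
            if ref_remaining[i] <= 0.0 and V[i] >= V_theta:
                V[i] = V_rest
                ref_remaining[i] = t_ref
                y_steps[i] = spike_width
                any_active = True
                if n_spk < cap:
                    spike_t[n_spk] = t_now
                    spike_i[n_spk] = i
                n_spk += 1
        # synaptic increments from all currently spiking neurons
        if any_active:
            if uniform_w:
                S = 0.0
                for j in range(N):
                    if y_steps[j] > 0:
                        S += 1.0
                for i in range(N):
                    yi = 1.0 if y_steps[i] > 0 else 0.0
                    g[i] += K[i] * (S - yi) / (N - 1)
            else:
                for j in range(N):
                    if y_steps[j] > 0:
                        for i in range(N):
                            g[i] += K[i] * w[i, j] / (N - 1)
            for i in range(N):
                if y_steps[i] > 0:
                    y_steps[i] -= 1
        if record and (step + 1) % record_stride == 0:
            for i in range(N):
                V_trace[rec_idx, i] = V[i]
                g_trace[rec_idx, i] = g[i]
            rec_idx += 1
    return n_spk, n_steps, -1


@dataclass
class SimulationResult:
    """Spike record plus the exact final state (for bit-exact continuation)."""

    spikes: SpikeRecord
    final_state: NetworkState
    t_trace: np.ndarray | None = None
    V_trace: np.ndarray | None = None
    g_trace: np.ndarray | None = None


def initial_state(params: NeuronParameters, N: int, seed: int | None = 0,
                  g_max: float = 1.0) -> NetworkState:
    """Random initial conditions: V ~ uniform[V_rest, V_theta), g ~ uniform[0, g_max].

    The initial conductance kick is what ignites the autonomous network: with
    g = 0 and every V below threshold the membrane potentials would only
    decay toward rest and no spike could ever occur.  g_max = 1 places most
    neurons transiently above the drive threshold
    (V_theta - V_rest)/(E_ex - V_theta); the kick decays within a few tau_ex,
    after which activity is either self-sustained or dies out.
    """
    rng = np.random.default_rng(seed)
    V = rng.uniform(params.V_rest, params.V_theta, size=N)
    g = rng.uniform(0.0, g_max, size=N)
    return NetworkState(
        t=0.0, V=V, g=g,
        y_steps=np.zeros(N, dtype=np.int64),
        ref_remaining=np.zeros(N),
    )


def _spike_capacity(N: int, duration: float, dt: float, t_ref: float) -> int:
    per_neuron = duration / max(t_ref, dt) + 2.0
    return int(N * per_neuron) + N


def simulate(params: NeuronParameters,
             coupling: CouplingConfig | np.ndarray,
             sim: SimulationConfig,
             weights: WeightMatrix | None = None,
             state: NetworkState | None = None) -> SimulationResult:
    """Run the network for ``sim.duration`` ms and collect all spike events.

    ``coupling`` may be a :class:`CouplingConfig` or a precomputed K array.
    ``weights`` defaults to the uniform matrix.  If ``state`` is given the run
    continues from it (times stay absolute); otherwise random initial
    conditions are drawn from ``sim.seed``.  Identical configurations and
    seeds reproduce the spike record bit-for-bit.
    """
    K = make_coupling(coupling) if isinstance(coupling, CouplingConfig) else np.asarray(coupling, float)
    N = len(K)
    if np.any(K < 0):
        raise ConfigError("coupling strengths must be nonnegative")
    if weights is not None and weights.N != N:
        raise ConfigError(f"weight matrix size {weights.N} != network size {N}")

    ss = np.random.SeedSequence(sim.seed)
    init_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if state is None:
        st = initial_state(params, N, init_seed)
    else:
        st = state.copy()

    uniform_w = weights is None or weights.is_uniform
    w = np.zeros((1, 1)) if uniform_w else weights.w

    n_steps = sim.n_steps
    cap = _spike_capacity(N, sim.duration, sim.dt, params.t_ref)
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)

    if sim.record_V:
        n_rec = n_steps // sim.record_stride
        V_trace = np.empty((n_rec, N))
        g_trace = np.empty((n_rec, N))
        stride = sim.record_stride
    else:
        V_trace = np.empty((0, N))
        g_trace = np.empty((0, N))
        stride = 0

    n_spk, last_step, bad = _run_kernel(
        st.V, st.g, st.y_steps, st.ref_remaining, K, w, uniform_w,
        sim.dt, n_steps, params.tau, params.tau_ex, params.V_rest,
        params.V_theta, params.E_ex, params.t_ref, params.spike_width_steps,
        sim.I_ext, sim.noise_sd, noise_seed, st.t, spike_t, spike_i,
        V_trace, g_trace, stride,
    )
    if bad >= 0:
        raise NumericalBlowupError(
            f"non-finite membrane potential for neuron {bad} "
            f"at t = {st.t + (last_step + 1) * sim.dt:.4f} ms"
        )
    if n_spk > cap:  # pragma: no cover - capacity is sized generously
        raise RuntimeError(f"spike buffer overflow: {n_spk} > {cap}")

    t_end = st.t + n_steps * sim.dt
    record = SpikeRecord(spike_i[:n_spk].copy(), spike_t[:n_spk].copy(), N, t_end)
    st.t = t_end
    result = SimulationResult(spikes=record, final_state=st)
    if sim.record_V:
        result.t_trace = st.t - n_steps * sim.dt + sim.dt * sim.record_stride * (
            1 + np.arange(V_trace.shape[0]))
        result.V_trace = V_trace
        result.g_trace = g_trace
    return result


def step(state: NetworkState,
         params: NeuronParameters,
         K: np.ndarray,
         weights: WeightMatrix | None,
         sim: SimulationConfig) -> tuple[NetworkState, np.ndarray]:
    """Advance the network by a single timestep.

    Returns the new state and the indices of neurons that spiked during the
    step.  This drives the same compiled kernel as :func:`simulate` and is
    mainly useful for tests and didactic traces.
    """
    st = state.copy()
    K = np.asarray(K, float)
    N = len(K)
    uniform_w = weights is None or weights.is_uniform
    w = np.zeros((1, 1)) if uniform_w else weights.w
    spike_t = np.empty(N)
    spike_i = np.empty(N, dtype=np.int64)
    dummyV = np.empty((0, N))
    n_spk, last_step, bad = _run_kernel(
        st.V, st.g, st.y_steps, st.ref_remaining, K, w, uniform_w,
        sim.dt, 1, params.tau, params.tau_ex, params.V_rest,
        params.V_theta, params.E_ex, params.t_ref, params.spike_width_steps,
        sim.I_ext, sim.noise_sd, sim.seed % (2**31), st.t,
        spike_t, spike_i, dummyV, dummyV.copy(), 0,
    )
    if bad >= 0:
        raise NumericalBlowupError(
            f"non-finite membrane potential for neuron {bad} at t = {st.t + sim.dt:.4f} ms"
        )
    st.t += sim.dt
    return st, spike_i[:n_spk].copy()
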
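"""Reproducible experiment drivers built on the simulator and classifiers.

Every protocol is deterministic given its seeds; result rows carry the seed
that produced them.  Parameter ramps are realized as dense piecewise-constant
chunks with the exact network state carried across chunk boundaries — a
discretized linear interpolation of the coupling parameters, slow enough
(enforced) to be adiabatic with respect to the network timescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (DEFAULT_MEASURE_MS, DEFAULT_TRANSIENT_MS, PhaseLabel,
                       RateProfile, classify_state, rates_from_spikes)
from .network import WeightMatrix, make_coupling, make_weights, simulate
from .params import CouplingConfig, NeuronParameters, SimulationConfig
from .records import NetworkState


def measure_state(params: NeuronParameters,
                  coupling: CouplingConfig,
                  sim: SimulationConfig,
                  weights: WeightMatrix | None = None,
                  t_transient: float = DEFAULT_TRANSIENT_MS,
                  t_measure: float = DEFAULT_MEASURE_MS,
                  state: NetworkState | None = None):
    """Simulate to dynamical equilibrium and measure the stationary profile.

    Runs t_transient + t_measure ms (continuing from ``state`` if given),
    computes the rate profile over the final t_measure ms and classifies it.
    Returns (profile, label, result).
    """
    run = sim.replace(duration=t_transient + t_measure)
    res = simulate(params, coupling, run, weights=weights, state=state)
    t0 = res.spikes.duration - t_measure
    profile = rates_from_spikes(res.spikes, t_transient=t0, t_measure=t_measure)
    label = classify_state(profile)
    return profile, label, res


@dataclass
class PhaseDiagram:
    """Grid of classified states over the coupling plane."""

    table: pd.DataFrame  # columns: K_mean, Delta_K, label, mean_rate_hz, seed

    def label_at(self, K_mean: float, Delta_K: float) -> str:
        t = self.table
        row = t[(np.isclose(t.K_mean, K_mean)) & (np.isclose(t.Delta_K, Delta_K))]
        return str(row.label.iloc[0])


def scan_phase_diagram(K_mean_values,
                       Delta_K_ratio_values,
                       params: NeuronParameters | None = None,
                       N: int = 100,
                       sim: SimulationConfig | None = None,
                       t_transient: float = DEFAULT_TRANSIENT_MS,
                       t_measure: float = DEFAULT_MEASURE_MS,
                       seed: int = 0,
                       continuation: bool = False) -> PhaseDiagram:
    """Classify the stationary state on a (K_mean, Delta_K/K_mean) grid.

    Each cell is simulated from random initial conditions (or, with
    ``continuation``, from the previous cell's final state along each
    Delta_K row) and classified from its settled rate profile.  Cells whose
    simulation fails are recorded with label 'failed'.
    """
    params = params or NeuronParameters()
    sim = sim or SimulationConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for ratio in np.atleast_1d(Delta_K_ratio_values):
        state = None
        for Kb in np.atleast_1d(K_mean_values):
            cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            coupling = CouplingConfig(N=N, K_mean=float(Kb),
                                      Delta_K=float(ratio * Kb))
            cell_sim = sim.replace(seed=cell_seed)
            try:
                profile, label, res = measure_state(
                    params, coupling, cell_sim,
                    t_transient=t_transient, t_measure=t_measure,
                    state=state if continuation else None)
                if continuation:
                    state = res.final_state
                rows.append({"K_mean": float(Kb), "Delta_K": float(ratio * Kb),
                             "Delta_K_ratio": float(ratio), "label": label.label,
                             "mean_rate_hz": profile.mean_rate_hz,
                             "seed": cell_seed})
            except Exception as exc:  # noqa: BLE001 - cell marked failed, scan continues
                rows.append({"K_mean": float(Kb), "Delta_K": float(ratio * Kb),
                             "Delta_K_ratio": float(ratio), "label": "failed",
                             "mean_rate_hz": np.nan, "seed": cell_seed,
                             "error": str(exc)})
    return PhaseDiagram(table=pd.DataFrame(rows))


@dataclass
class AdiabaticPath:
    """Piecewise-linear path through (K_mean, Delta_K) coupling space.

    ``points`` are the visited parameter vertices; between consecutive
    vertices the parameters are ramped linearly over ``ramp_duration`` ms
    (chunked piecewise-constant every ``chunk_ms``).  At each vertex the
    parameters are frozen for ``settle_ms`` + ``measure_ms`` and the rate
    profile measured in the frozen window.
    """

    points: list[tuple[float, float]]
    ramp_duration: float = 20000.0
    settle_ms: float = 1000.0
    measure_ms: float = 5000.0
    chunk_ms: float = 100.0


@dataclass
class AdiabaticWindow:
    """One frozen observation window along an adiabatic path."""

    index: int
    K_mean: float
    Delta_K: float
    profile: RateProfile
    label: PhaseLabel
    t_start: float


def run_adiabatic(path: AdiabaticPath,
                  params: NeuronParameters | None = None,
                  N: int = 100,
                  sim: SimulationConfig | None = None,
                  seed: int = 0) -> list[AdiabaticWindow]:
    """Follow an adiabatic parameter path, measuring in frozen windows.

    The network state is carried continuously across ramps and windows; only
    the couplings change.  Ramps must be slow: ramp_duration >= 100 tau is
    enforced as the adiabaticity floor.
    """
    params = params or NeuronParameters()
    sim = sim or SimulationConfig()
    if path.ramp_duration < 100.0 * params.tau:
        raise ValueError(
            f"ramp_duration {path.ramp_duration} ms is too fast to be adiabatic "
            f"(need >= 100 tau = {100 * params.tau} ms)"
        )
    sim = sim.replace(seed=seed)

    windows: list[AdiabaticWindow] = []
    state: NetworkState | None = None
    for idx, (Kb, dK) in enumerate(path.points):
        if state is not None:
            prev = path.points[idx - 1]
            n_chunks = max(1, int(round(path.ramp_duration / path.chunk_ms)))
            for c in range(n_chunks):
                f = (c + 1) / n_chunks
                Kb_c = prev[0] + f * (Kb - prev[0])
                dK_c = prev[1] + f * (dK - prev[1])
                coupling = CouplingConfig(N=N, K_mean=Kb_c, Delta_K=dK_c)
                res = simulate(params, coupling,
                               sim.replace(duration=path.ramp_duration / n_chunks),
                               state=state)
                state = res.final_state
        coupling = CouplingConfig(N=N, K_mean=Kb, Delta_K=dK)
        profile, label, res = measure_state(
            params, coupling, sim,
            t_transient=path.settle_ms, t_measure=path.measure_ms, state=state)
        state = res.final_state
        windows.append(AdiabaticWindow(
            index=idx, K_mean=Kb, Delta_K=dK, profile=profile, label=label,
            t_start=state.t - path.measure_ms))
    return windows


def hysteresis_gap(forward: list[AdiabaticWindow],
                   backward: list[AdiabaticWindow]) -> pd.DataFrame:
    """Max per-rank relative rate gap between legs at matched parameters.

    Matches windows by (K_mean, Delta_K) and reports, per matched point, the
    maximal |rate_fwd - rate_bwd| / mean over ranks.  Gaps above ~5% flag an
    irreversible (hysteretic) transition.
    """
    rows = []
    for wf in forward:
        for wb in backward:
            if np.isclose(wf.K_mean, wb.K_mean) and np.isclose(wf.Delta_K, wb.Delta_K):
                a, b = wf.profile.rate_hz, wb.profile.rate_hz
                scale = max(np.mean(a), np.mean(b), 1e-9)
                rows.append({"K_mean": wf.K_mean, "Delta_K": wf.Delta_K,
                             "max_gap_rel": float(np.max(np.abs(a - b)) / scale)})
    return pd.DataFrame(rows)


def input_ramp(I_values_positive,
               I_values_negative,
               params: NeuronParameters | None = None,
               coupling: CouplingConfig | None = None,
               sim: SimulationConfig | None = None,
               settle_ms: float = 1000.0,
               measure_ms: float = 5000.0,
               seed: int = 0):
    """Adiabatic external-input excursions from I_ext = 0.

    Two excursions start from the settled unperturbed state: one stepping
    through the positive levels, one through the negative levels (each
    monotone, state carried along).  Returns (DataFrame, profiles) with one
    row per level: I_ext, direction, mean rate, active fraction, seed.
    """
    params = params or NeuronParameters()
    # drifting-state anchor: robust baseline for input perturbations
    coupling = coupling or CouplingConfig(N=100, K_mean=3.0, Delta_K=1.8)
    sim = (sim or SimulationConfig()).replace(seed=seed)

    profile0, label0, res0 = measure_state(params, coupling, sim,
                                           t_transient=2 * settle_ms,
                                           t_measure=measure_ms)
    base_state = res0.final_state
    rows = [{"I_ext": 0.0, "direction": "baseline",
             "mean_rate_hz": profile0.mean_rate_hz,
             "active_fraction": float(np.mean(profile0.rate_hz >= 1.0)),
             "label": label0.label, "seed": sim.seed}]
    profiles = {(0.0, "baseline"): profile0}
    for direction, levels in (("up", I_values_positive), ("down", I_values_negative)):
        state = base_state.copy()
        for I in levels:
            lvl_sim = sim.replace(I_ext=float(I))
            profile, label, res = measure_state(
                params, coupling, lvl_sim,
                t_transient=settle_ms, t_measure=measure_ms, state=state)
            state = res.final_state
            rows.append({"I_ext": float(I), "direction": direction,
                         "mean_rate_hz": profile.mean_rate_hz,
                         "active_fraction": float(np.mean(profile.rate_hz >= 1.0)),
                         "label": label.label, "seed": sim.seed})
            profiles[(float(I), direction)] = profile
    return pd.DataFrame(rows), profiles


@dataclass
class EnsembleProfile:
    """Per-rank mean and standard deviation of rates over weight draws."""

    k_rank: np.ndarray
    mean_rate_hz: np.ndarray
    sd_rate_hz: np.ndarray
    rates: np.ndarray  # (n_realizations, N)
    seeds: list[int]


def jitter_ensemble(jitter_width: float,
                    n_realizations: int,
                    params: NeuronParameters | None = None,
                    coupling: CouplingConfig | None = None,
                    sim: SimulationConfig | None = None,
                    t_transient: float = DEFAULT_TRANSIENT_MS,
                    t_measure: float = DEFAULT_MEASURE_MS,
                    seed: int = 0,
                    common_dynamics_seed: bool = True) -> EnsembleProfile:
    """Rate statistics over an ensemble of jittered weight matrices.

    Draws ``n_realizations`` independent weight matrices with entries
    1 + eta, eta ~ flat(-jitter_width, +jitter_width), simulates each to
    equilibrium, and reports the per-rank mean and standard deviation of the
    firing rates.  With ``common_dynamics_seed`` the initial conditions are
    shared across realizations, isolating the weight variability.
    """
    params = params or NeuronParameters()
    coupling = coupling or CouplingConfig(N=100, K_mean=3.0, Delta_K=1.8)
    sim = sim or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    weight_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_realizations)]
    rates = []
    for k, wseed in enumerate(weight_seeds):
        w = make_weights(coupling.N, jitter_width, seed=wseed)
        dyn_seed = sim.seed if common_dynamics_seed else wseed
        profile, _, _ = measure_state(params, coupling, sim.replace(seed=dyn_seed),
                                      weights=w, t_transient=t_transient,
                                      t_measure=t_measure)
        rates.append(profile.rate_hz)
    rates = np.array(rates)
    rank = (1.0 + np.arange(coupling.N)) / coupling.N
    return EnsembleProfile(k_rank=rank, mean_rate_hz=rates.mean(axis=0),
                           sd_rate_hz=rates.std(axis=0), rates=rates,
                           seeds=weight_seeds)


def size_scaling(N_values,
                 K_mean: float,
                 Delta_K_ratio: float,
                 params: NeuronParameters | None = None,
                 sim: SimulationConfig | None = None,
                 t_transient: float = DEFAULT_TRANSIENT_MS,
                 t_measure: float = DEFAULT_MEASURE_MS,
                 seed: int = 0) -> dict[int, RateProfile]:
    """Rate-vs-rank profiles at several network sizes, common rank axis.

    The coupling scaling K_i/(N-1) makes the profiles size-invariant up to
    finite-size fluctuations; overlaying them checks that invariance.
    """
    N_values = [int(n) for n in N_values]
    params = params or NeuronParameters()
    sim = sim or SimulationConfig()
    out: dict[int, RateProfile] = {}
    ss = np.random.SeedSequence(seed)
    for N, child in zip(N_values, ss.spawn(len(N_values))):
        coupling = CouplingConfig(N=int(N), K_mean=K_mean,
                                  Delta_K=Delta_K_ratio * K_mean)
        run_seed = int(child.generate_state(1)[0] % (2**31))
        profile, _, _ = measure_state(params, coupling, sim.replace(seed=run_seed),
                                      t_transient=t_transient, t_measure=t_measure)
        out[int(N)] = profile
    return out
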
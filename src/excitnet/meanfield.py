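"""Stationary mean-field (SMF) theory of the asynchronous drifting state.

In the drifting state the network-averaged firing activity r_bar (spikes/ms)
is constant in time, so each neuron sees a constant synaptic input.  Its
conductance then settles at g* = tau_ex K r_bar and the membrane equation
becomes linear,

    tau dV/dt = (V_rest - V) + g* (E_ex - V) = tau (A - B V),

with A = (V_rest + g* E_ex)/tau and B = (1 + g*)/tau.  Starting from rest the
time to threshold is

    t* = -(1/B) log((B V_theta - A) / (B V_rest - A)),

finite only when K r_bar exceeds the drive threshold
(1/tau_ex)(V_theta - V_rest)/(E_ex - V_theta); the neuron then fires
periodically at rate 1/(t* + t_ref).  Averaging the predicted rates over the
coupling distribution (silent neurons counted as zero) maps r_bar to a new
network rate; a fixed point of this map is the SMF solution, exact in the
thermodynamic limit for drifting states but not when synchronized clusters
are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import NeuronParameters


def drive_threshold(params: NeuronParameters) -> float:
    """Minimal K*r_bar (1/ms) for the threshold to be reachable.

    Below this value of the product K_i * r_bar the steady-state membrane
    potential stays under V_theta and the neuron never fires.
    """
    return (params.V_theta - params.V_rest) / (
        params.tau_ex * (params.E_ex - params.V_theta))


def steady_conductance(K, r_bar: float, params: NeuronParameters):
    """Steady-state conductance g* = tau_ex * K * r_bar (r_bar in 1/ms)."""
    K = np.asarray(K, float)
    if np.any(K < 0) or r_bar < 0:
        raise ValueError("K and r_bar must be nonnegative")
    return params.tau_ex * K * r_bar


def time_to_threshold(K, r_bar: float, params: NeuronParameters):
    """Closed-form time t* (ms) for V to climb from rest to threshold.

    Returns inf where the drive K*r_bar does not exceed the firing
    threshold (the bound itself maps to inf: t* diverges continuously).
    Accepts scalars or arrays in K.
    """
    K = np.asarray(K, float)
    scalar = K.ndim == 0
    K = np.atleast_1d(K)
    if np.any(K < 0) or r_bar < 0:
        raise ValueError("K and r_bar must be nonnegative")
    g_star = params.tau_ex * K * r_bar
    A = (params.V_rest + g_star * params.E_ex) / params.tau
    B = (1.0 + g_star) / params.tau
    t_star = np.full(K.shape, np.inf)
    num = B * params.V_theta - A
    den = B * params.V_rest - A
    fires = K * r_bar > drive_threshold(params)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -np.log(num / den) / B
    t_star[fires] = t[fires]
    return float(t_star[0]) if scalar else t_star


def predicted_rates(K, r_bar: float, params: NeuronParameters):
    """Per-neuron periodic firing rate 1/(t* + t_ref) in 1/ms (0 if silent)."""
    t_star = np.atleast_1d(time_to_threshold(K, r_bar, params))
    rates = np.zeros(t_star.shape)
    finite = np.isfinite(t_star)
    rates[finite] = 1.0 / (t_star[finite] + params.t_ref)
    return rates


def smf_map(r_bar: float, K, params: NeuronParameters) -> float:
    """One application of the self-consistency map: mean predicted rate.

    The average runs over all N neurons, with non-firing neurons contributing
    zero — required for partially inactive states to be self-consistent.
    """
    return float(np.mean(predicted_rates(K, r_bar, params)))


@dataclass
class MeanFieldSolution:
    """Self-consistent stationary mean field and its per-neuron consequences.

    ``r_bar`` is in spikes/ms; ``rate_hz`` = 1000/(t* + t_ref) per neuron
    (zero for silent neurons); ``g_star`` = tau_ex K r_bar.  ``all_roots``
    lists every bracketed fixed point of the map (r_bar is the largest).
    """

    r_bar: float
    K: np.ndarray
    t_star: np.ndarray
    rate_hz: np.ndarray
    g_star: np.ndarray
    residual: float
    all_roots: list[float] = field(default_factory=list)

    @property
    def r_bar_hz(self) -> float:
        return 1000.0 * self.r_bar

    @property
    def silent(self) -> np.ndarray:
        """Boolean mask of neurons predicted never to fire."""
        return ~np.isfinite(self.t_star)


def solve_self_consistent(K, params: NeuronParameters,
                          n_grid: int = 2000,
                          tol: float = 1e-10) -> MeanFieldSolution:
    """Largest fixed point of the SMF map on [0, 1/t_ref].

    The map is nondecreasing in r_bar and bounded by 1/t_ref, so scanning the
    residual r - smf_map(r) downward from 1/t_ref and bisecting the first
    sign change brackets the largest root.  When no positive fixed point
    exists the trivial silent solution r_bar = 0 is returned.
    """
    K = np.asarray(K, float)
    if params.t_ref <= 0:
        raise ValueError("SMF fixed point requires t_ref > 0 (no rate ceiling otherwise)")
    r_hi = 1.0 / params.t_ref

    def h(r: float) -> float:
        return r - smf_map(r, K, params)

    grid = np.linspace(r_hi, 0.0, n_grid, endpoint=False)
    hvals = np.array([h(r) for r in grid])
    roots: list[float] = []
    for a, b, ha, hb in zip(grid[1:], grid[:-1], hvals[1:], hvals[:-1]):
        if ha == 0.0:
            roots.append(float(a))
        elif ha * hb < 0:
            roots.append(float(brentq(h, a, b, xtol=tol)))
    roots = sorted(set(roots))
    r_star = roots[-1] if roots else 0.0

    t_star = np.atleast_1d(time_to_threshold(K, r_star, params))
    rates = predicted_rates(K, r_star, params)
    return MeanFieldSolution(
        r_bar=r_star,
        K=K,
        t_star=t_star,
        rate_hz=1000.0 * rates,
        g_star=steady_conductance(K, r_star, params),
        residual=abs(h(r_star)),
        all_roots=[0.0] + roots,
    )


def solve_self_consistent_continuum(K_mean: float, Delta_K: float,
                                    params: NeuronParameters,
                                    n_nodes: int = 256,
                                    **kwargs) -> MeanFieldSolution:
    """Thermodynamic-limit SMF: the average over the flat K-distribution.

    Evaluates the self-consistency average as a Gauss-Legendre quadrature
    over K ~ flat[K_mean - Delta_K, K_mean + Delta_K] instead of an N-point
    sum (the two coincide as N grows).
    """
    if Delta_K == 0:
        nodes = np.array([K_mean])
    else:
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        nodes = K_mean + Delta_K * x
        # equal quadrature weights are folded in by a weighted mean below
        sol = _solve_weighted(nodes, w / 2.0, params, **kwargs)
        return sol
    return solve_self_consistent(nodes, params, **kwargs)


def _solve_weighted(K_nodes, weights, params, n_grid: int = 2000,
                    tol: float = 1e-10) -> MeanFieldSolution:
    weights = np.asarray(weights, float)

    def wmap(r: float) -> float:
        return float(np.sum(weights * predicted_rates(K_nodes, r, params)))

    def h(r: float) -> float:
        return r - wmap(r)

    r_hi = 1.0 / params.t_ref
    grid = np.linspace(r_hi, 0.0, n_grid, endpoint=False)
    hvals = np.array([h(r) for r in grid])
    roots = []
    for a, b, ha, hb in zip(grid[1:], grid[:-1], hvals[1:], hvals[:-1]):
        if ha * hb < 0:
            roots.append(float(brentq(h, a, b, xtol=tol)))
    r_star = max(roots) if roots else 0.0
    t_star = np.atleast_1d(time_to_threshold(K_nodes, r_star, params))
    return MeanFieldSolution(
        r_bar=r_star, K=np.asarray(K_nodes, float), t_star=t_star,
        rate_hz=1000.0 * predicted_rates(K_nodes, r_star, params),
        g_star=steady_conductance(K_nodes, r_star, params),
        residual=abs(h(r_star)), all_roots=[0.0] + sorted(roots),
    )


def phase_boundaries(Delta_K_values, params: NeuronParameters,
                     N: int = 100,
                     K_max: float = 20.0,
                     tol: float = 1e-6):
    """Analytic SMF phase-boundary curves in the (K_mean, Delta_K) plane.

    For each Delta_K two critical mean couplings are located by bisection:

    * ``K_inactive``: smallest K_mean for which a positive fixed point of the
      SMF map exists (inactive <-> partially-inactive transition);
    * ``K_all_active``: smallest K_mean for which even the weakest neuron,
      K_min = K_mean - Delta_K, satisfies the firing condition at the
      self-consistent rate (partially-inactive <-> fully drifting).

    Returns a pandas DataFrame with columns Delta_K, K_inactive, K_all_active
    (NaN where a boundary lies outside (Delta_K, K_max]).
    """
    import pandas as pd

    from .network import make_coupling
    from .params import CouplingConfig

    bound = drive_threshold(params)
    rows = []
    for dK in np.atleast_1d(Delta_K_values):

        def K_of(Kb: float) -> np.ndarray:
            cfg = CouplingConfig(N=N, K_mean=Kb, Delta_K=min(dK, Kb * (1 - 1e-12)),
                                 scheme="equidistant")
            return make_coupling(cfg)

        def active(Kb: float) -> float:
            sol = solve_self_consistent(K_of(Kb), params, n_grid=400)
            return 1.0 if sol.r_bar > 0 else -1.0

        def all_active(Kb: float) -> float:
            sol = solve_self_consistent(K_of(Kb), params, n_grid=400)
            if sol.r_bar == 0:
                return -1.0
            return (Kb - dK) * sol.r_bar - bound

        K_lo = max(dK, 1e-6)
        K_in = _bisect_threshold(active, K_lo, K_max, tol)
        K_all = _bisect_threshold(all_active, K_lo, K_max, tol)
        rows.append({"Delta_K": float(dK), "K_inactive": K_in, "K_all_active": K_all})
    return pd.DataFrame(rows)


def _bisect_threshold(f, lo: float, hi: float, tol: float) -> float:
    """Smallest x in (lo, hi] with f(x) > 0, assuming f nondecreasing; NaN if none."""
    if f(hi) <= 0:
        return float("nan")
    if f(lo) > 0:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
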
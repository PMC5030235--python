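"""Rate profiles, interspike-interval statistics, and state classification.

The network's self-organized states are read off the stationary rate-vs-rank
profile: neurons are ordered by afferent coupling strength K_i and their
firing rates plotted against the relative rank i/N.  Five states occur —
inactive (I), partially inactive + drifting (I+D), fully drifting (D), mixed
drifting + synchronized (D+S), and fully synchronized (S).  A synchronized
cluster shows up as a plateau of identical rates; drifting neurons form a
continuum; inactive neurons sit at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SpikeRecord

#: measurement defaults: discard the settling transient, then measure.
DEFAULT_TRANSIENT_MS = 2000.0
DEFAULT_MEASURE_MS = 10000.0


@dataclass
class RateProfile:
    """Per-neuron firing rates (Hz) in coupling-rank order."""

    rate_hz: np.ndarray
    k_rank: np.ndarray  # relative rank i/N in (0, 1]
    t_measure: float    # ms

    @property
    def N(self) -> int:
        return len(self.rate_hz)

    @property
    def mean_rate_hz(self) -> float:
        return float(np.mean(self.rate_hz))


def rates_from_spikes(record: SpikeRecord,
                      t_transient: float = DEFAULT_TRANSIENT_MS,
                      t_measure: float = DEFAULT_MEASURE_MS) -> RateProfile:
    """Firing rates from spike counts in the post-transient window.

    The window is [t_transient, t_transient + t_measure); rates are
    count/t_measure in Hz.  The window must fit within the record.
    """
    if t_measure <= 0:
        raise ValueError("t_measure must be > 0")
    if t_transient + t_measure > record.duration + 1e-9:
        raise ValueError(
            f"measurement window [{t_transient}, {t_transient + t_measure}) ms "
            f"exceeds record duration {record.duration} ms"
        )
    counts = record.counts(t_transient, t_transient + t_measure)
    rate_hz = counts * 1000.0 / t_measure
    rank = (1.0 + np.arange(record.N)) / record.N
    return RateProfile(rate_hz=rate_hz, k_rank=rank, t_measure=t_measure)


@dataclass
class ISIStatistics:
    """Per-neuron interspike-interval statistics and the pooled histogram.

    ``CV`` is the coefficient of variation sigma/T per neuron — zero for
    perfectly periodic firing, near one for Poisson-like firing.  Neurons
    with fewer than two spikes in the window are excluded (NaN entries) and
    listed in ``excluded``.  The histogram is the network average of the
    per-neuron densities of the normalized interval s/T_i.
    """

    intervals: list[np.ndarray]
    T: np.ndarray
    sigma: np.ndarray
    CV: np.ndarray
    excluded: list[int]
    hist_density: np.ndarray
    hist_edges: np.ndarray


def isi_statistics(record: SpikeRecord,
                   neurons=None,
                   t_transient: float = DEFAULT_TRANSIENT_MS,
                   n_bins: int = 100,
                   s_over_T_max: float = 3.0) -> ISIStatistics:
    """ISI lists, mean T_i, sigma_i and CV_i = sigma_i/T_i per neuron.

    Only spikes after ``t_transient`` enter.  The normalized-ISI histogram
    uses ``n_bins`` bins over s/T in [0, s_over_T_max], density-normalized
    per neuron and then averaged over analyzed neurons.
    """
    if neurons is None:
        neurons = range(record.N)
    neurons = list(neurons)
    per_times = record.per_neuron_times()

    edges = np.linspace(0.0, s_over_T_max, n_bins + 1)
    T = np.full(record.N, np.nan)
    sigma = np.full(record.N, np.nan)
    CV = np.full(record.N, np.nan)
    intervals: list[np.ndarray] = [np.empty(0) for _ in range(record.N)]
    excluded: list[int] = []
    densities = []
    for i in neurons:
        times = per_times[i]
        times = times[times >= t_transient]
        if len(times) < 2:
            excluded.append(i)
            continue
        isi = np.diff(times)
        intervals[i] = isi
        T[i] = isi.mean()
        sigma[i] = isi.std()
        CV[i] = sigma[i] / T[i]
        d, _ = np.histogram(isi / T[i], bins=edges, density=True)
        densities.append(d)
    density = (np.mean(densities, axis=0) if densities
               else np.zeros(n_bins))
    return ISIStatistics(intervals=intervals, T=T, sigma=sigma, CV=CV,
                         excluded=excluded, hist_density=density,
                         hist_edges=edges)


@dataclass
class PhaseLabel:
    """Classification of a stationary rate profile into the state taxonomy.

    ``label`` is assembled from the nonzero population fractions: 'I'
    (inactive), 'D' (drifting) and 'S' (synchronized plateau) joined by '+'.
    ``fractions`` = (inactive, drifting, synchronized), summing to 1.
    ``cluster`` holds the neuron indices of the synchronized plateau, if any.
    """

    label: str
    fractions: tuple[float, float, float]
    cluster: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def is_active(self) -> bool:
        return self.label != "I"


def _longest_plateau(rates: np.ndarray, active: np.ndarray,
                     rel_tol: float) -> tuple[int, int]:
    """Longest run [i0, i1) of consecutive active neurons with rates pairwise
    within rel_tol (measured as (max-min)/mean of the run).  O(N^2), fine for
    the network sizes in play."""
    N = len(rates)
    best = (0, 0)
    i = 0
    while i < N:
        if not active[i]:
            i += 1
            continue
        lo = hi = rates[i]
        j = i
        while j + 1 < N and active[j + 1]:
            nlo = min(lo, rates[j + 1])
            nhi = max(hi, rates[j + 1])
            if (nhi - nlo) > rel_tol * 0.5 * (nhi + nlo):
                break
            lo, hi = nlo, nhi
            j += 1
        if (j + 1 - i) > (best[1] - best[0]):
            best = (i, j + 1)
        i += 1
    return best


def classify_state(profile: RateProfile,
                   rate_floor_hz: float = 1.0,
                   rel_tol: float = 0.005,
                   min_cluster: int | None = None) -> PhaseLabel:
    """Label a stationary rate profile as I / I+D / D / D+S / S.

    Neurons below ``rate_floor_hz`` are inactive.  The longest run of
    consecutive-rank active neurons whose rates agree pairwise within
    ``rel_tol`` (relative) is a synchronized plateau if it spans at least
    ``min_cluster`` neurons (default max(3, 5% of N)); remaining active
    neurons are drifting.  Synchrony is thus diagnosed operationally from
    rate equality; any finite pairwise phase lags within a plateau do not
    affect the label.
    """
    rates = np.asarray(profile.rate_hz, float)
    N = len(rates)
    if min_cluster is None:
        min_cluster = max(3, int(np.ceil(0.05 * N)))
    active = rates >= rate_floor_hz
    n_inactive = int(np.sum(~active))

    i0, i1 = _longest_plateau(rates, active, rel_tol)
    cluster = np.arange(i0, i1) if (i1 - i0) >= min_cluster else np.empty(0, dtype=int)
    n_sync = len(cluster)
    n_drift = int(np.sum(active)) - n_sync

    parts = []
    if n_inactive > 0:
        parts.append("I")
    if n_drift > 0:
        parts.append("D")
    if n_sync > 0:
        parts.append("S")
    label = "+".join(parts) if parts else "I"
    if label == "I" and n_inactive == N:
        label = "I"
    return PhaseLabel(
        label=label,
        fractions=(n_inactive / N, n_drift / N, n_sync / N),
        cluster=cluster,
    )
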
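"""Spike-event containers — the sole currency exchanged between modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpikeRecord:
    """Ordered spike events of one simulation (or one imported spike table).

    Attributes
    ----------
    neuron : ndarray of int
        Neuron index of each event, 0-based.
    time : ndarray of float
        Spike time of each event, ms; globally sorted by time, ties by
        neuron index.
    N : int
        Network size (neuron indices run over 0..N-1).
    duration : float
        Total recorded span, ms.
    """

    neuron: np.ndarray
    time: np.ndarray
    N: int
    duration: float

    def __post_init__(self) -> None:
        self.neuron = np.asarray(self.neuron, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.neuron.shape != self.time.shape:
            raise ValueError("neuron and time arrays must have equal length")
        order = np.lexsort((self.neuron, self.time))
        self.neuron = self.neuron[order]
        self.time = self.time[order]

    def __len__(self) -> int:
        return len(self.time)

    def spikes_of(self, i: int) -> np.ndarray:
        """Sorted spike times of neuron ``i``, ms."""
        return self.time[self.neuron == i]

    def per_neuron_times(self) -> list[np.ndarray]:
        """Spike times split by neuron, one sorted array per neuron."""
        out: list[np.ndarray] = [np.empty(0) for _ in range(self.N)]
        if len(self.time) == 0:
            return out
        order = np.argsort(self.neuron, kind="stable")
        nrn = self.neuron[order]
        tms = self.time[order]
        bounds = np.searchsorted(nrn, np.arange(self.N + 1))
        for i in range(self.N):
            out[i] = np.sort(tms[bounds[i]:bounds[i + 1]])
        return out

    def isis_of(self, i: int) -> np.ndarray:
        """Interspike intervals of neuron ``i``, ms."""
        return np.diff(self.spikes_of(i))

    def counts(self, t_min: float = 0.0, t_max: float | None = None) -> np.ndarray:
        """Per-neuron spike counts within [t_min, t_max)."""
        if t_max is None:
            t_max = self.duration
        sel = (self.time >= t_min) & (self.time < t_max)
        return np.bincount(self.neuron[sel], minlength=self.N)

    def window(self, t_min: float, t_max: float) -> "SpikeRecord":
        """Sub-record of events with t_min <= t < t_max (times kept absolute)."""
        sel = (self.time >= t_min) & (self.time < t_max)
        return SpikeRecord(self.neuron[sel], self.time[sel], self.N, self.duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron, "spike_time_ms": self.time})

    @classmethod
    def empty(cls, N: int, duration: float) -> "SpikeRecord":
        return cls(np.empty(0, dtype=np.int64), np.empty(0), N, duration)


@dataclass
class NetworkState:
    """Instantaneous dynamical state, sufficient to restart a run exactly.

    ``V`` is the membrane potential (mV), ``g`` the dimensionless synaptic
    conductance, ``y_steps`` the remaining number of steps the spike indicator
    stays raised (y = 1 iff y_steps > 0), and ``ref_remaining`` the remaining
    refractory time (ms) during which V is clamped at rest.
    """

    t: float
    V: np.ndarray
    g: np.ndarray
    y_steps: np.ndarray
    ref_remaining: np.ndarray

    @property
    def y(self) -> np.ndarray:
        return (self.y_steps > 0).astype(np.int64)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.t, self.V.copy(), self.g.copy(),
            self.y_steps.copy(), self.ref_remaining.copy(),
        )
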
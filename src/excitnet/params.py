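"""Configuration dataclasses for the excitatory COBA integrate-and-fire network.

All internal times are milliseconds and voltages millivolts; firing rates are
carried internally in spikes/ms (1/ms) and converted to Hz only at reporting
boundaries (factor 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class NeuronParameters:
    """Membrane and synapse constants of a single excitable unit.

    Parameters
    ----------
    tau : float
        Membrane time constant, ms.
    tau_ex : float
        Excitatory conductance time constant, ms.
    V_rest : float
        Resting (and reset) potential, mV.
    V_theta : float
        Firing threshold, mV.
    E_ex : float
        Excitatory reversal potential, mV.
    t_ref : float
        Absolute refractory period during which the membrane equation is
        suspended and V is clamped at rest, ms.  This is the sole
        activity-limiting mechanism of the purely excitatory network.
    spike_width_steps : int
        Number of timesteps a spike (y = 1) lasts.
    """

    tau: float = 20.0
    tau_ex: float = 5.0
    V_rest: float = -60.0
    V_theta: float = -50.0
    E_ex: float = 0.0
    t_ref: float = 5.0
    spike_width_steps: int = 1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        if self.tau_ex <= 0:
            raise ConfigError(f"tau_ex must be > 0, got {self.tau_ex}")
        if not (self.V_rest < self.V_theta < self.E_ex):
            raise ConfigError(
                "require V_rest < V_theta < E_ex, got "
                f"{self.V_rest}, {self.V_theta}, {self.E_ex}"
            )
        if self.t_ref < 0:
            raise ConfigError(f"t_ref must be >= 0, got {self.t_ref}")
        if self.spike_width_steps < 1:
            raise ConfigError(
                f"spike_width_steps must be >= 1, got {self.spike_width_steps}"
            )

    @property
    def rate_ceiling_hz(self) -> float:
        """Maximal attainable firing rate 1000/t_ref in Hz (inf if t_ref = 0)."""
        return float("inf") if self.t_ref == 0 else 1000.0 / self.t_ref

    def replace(self, **kwargs) -> "NeuronParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CouplingConfig:
    """Afferent coupling-strength distribution K_i across the network.

    ``equidistant`` places the K_i on a uniform lattice spanning
    [K_mean - Delta_K, K_mean + Delta_K]; ``flat_random`` draws them from the
    flat distribution on the same interval (and sorts them ascending, so that
    neuron index doubles as coupling rank in both schemes).
    """

    N: int = 100
    K_mean: float = 2.0
    Delta_K: float = 0.0
    scheme: str = "equidistant"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigError(f"N must be >= 2, got {self.N}")
        if self.K_mean <= 0:
            raise ConfigError(f"K_mean must be > 0, got {self.K_mean}")
        if not (0 <= self.Delta_K <= self.K_mean):
            raise ConfigError(
                "Delta_K must lie in [0, K_mean] (couplings are nonnegative), "
                f"got Delta_K={self.Delta_K}, K_mean={self.K_mean}"
            )
        if self.scheme not in ("equidistant", "flat_random"):
            raise ConfigError(f"unknown coupling scheme {self.scheme!r}")

    def replace(self, **kwargs) -> "CouplingConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for a fixed-timestep run."""

    dt: float = 0.01          # ms
    duration: float = 1000.0  # ms
    I_ext: float = 0.0        # mV, constant external drive
    noise_sd: float = 0.0     # mV*ms^(1/2), additive Gaussian membrane noise
    seed: int = 0
    record_V: bool = False
    record_stride: int = 100  # store every record_stride-th V sample

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.duration <= 0:
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.record_stride < 1:
            raise ConfigError(f"record_stride must be >= 1, got {self.record_stride}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
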
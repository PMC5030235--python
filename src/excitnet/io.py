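"""Config parsing, seeded-RNG bookkeeping, and plain-text table I/O.

All on-disk artifacts are text: spike tables and derived results are headered
TSV, configs are YAML with flat sections mirroring the dataclasses, and each
run can write a JSON manifest of fully resolved parameters and seeds that is
sufficient to reproduce it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ConfigError, CouplingConfig, NeuronParameters, SimulationConfig
from .records import SpikeRecord

_TIME_FMT = "%.6f"  # ms with 6 decimals: resolves dt = 0.001 ms exactly


def write_spikes(record: SpikeRecord, path) -> None:
    """Write a spike record as headered TSV (neuron_id, spike_time_ms).

    Rows are sorted by time, ties broken by neuron id; times carry 6
    decimals so the reader round-trips them exactly.
    """
    df = record.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=_TIME_FMT)


def read_spikes(path, N: int | None = None, duration: float | None = None) -> SpikeRecord:
    """Read a spike TSV written by :func:`write_spikes` (or any table with
    the same two columns).  N and duration default to the observed maxima."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"neuron_id": np.int64,
                                                "spike_time_ms": np.float64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ConfigError(f"malformed spike table {path}: {exc}") from exc
    if list(df.columns) != ["neuron_id", "spike_time_ms"]:
        raise ConfigError(
            f"spike table {path} must have columns neuron_id, spike_time_ms, "
            f"got {list(df.columns)}"
        )
    if N is None:
        N = int(df.neuron_id.max()) + 1 if len(df) else 1
    if duration is None:
        duration = float(df.spike_time_ms.max()) if len(df) else 0.0
    return SpikeRecord(df.neuron_id.to_numpy(), df.spike_time_ms.to_numpy(),
                       N=N, duration=duration)


@dataclass
class WeightsSection:
    """Weight-matrix settings: jitter half-width and optional renormalization."""

    jitter_width: float = 0.0
    renormalize: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisSection:
    """Measurement-window and classifier settings."""

    t_transient: float = 2000.0
    t_measure: float = 10000.0
    rate_floor_hz: float = 1.0
    rel_tol: float = 0.005

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentConfig:
    """Aggregated, validated configuration for one experiment."""

    neuron: NeuronParameters = field(default_factory=NeuronParameters)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    weights: WeightsSection = field(default_factory=WeightsSection)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    def to_dict(self) -> dict:
        return {
            "neuron": self.neuron.to_dict(),
            "coupling": self.coupling.to_dict(),
            "weights": self.weights.to_dict(),
            "simulation": self.simulation.to_dict(),
            "analysis": self.analysis.to_dict(),
        }


_SECTIONS = {
    "neuron": NeuronParameters,
    "coupling": CouplingConfig,
    "weights": WeightsSection,
    "simulation": SimulationConfig,
    "analysis": AnalysisSection,
}


def load_config(path) -> ExperimentConfig:
    """Load a YAML experiment config, filling defaults and validating.

    Unknown sections or keys are rejected with an error naming them; every
    dataclass invariant is enforced on construction.  An empty file yields
    the full default configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping of sections")
    kwargs = {}
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ConfigError(
                f"unknown config section {section!r}; "
                f"expected one of {sorted(_SECTIONS)}"
            )
        cls = _SECTIONS[section]
        payload = payload or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in section {section!r}; "
                f"valid keys: {sorted(valid)}"
            )
        kwargs[section] = cls(**payload)
    return ExperimentConfig(**kwargs)


def save_config(config: ExperimentConfig, path) -> None:
    """Write a config as YAML; load(save(c)) == c."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def spawn_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    """Independent per-component seeds from one master seed.

    Each named component (initial conditions, weight jitter, noise, ...)
    receives its own stream, so toggling one randomness source does not
    shift the draws of the others.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(names, children)}


def write_manifest(path, config: ExperimentConfig | dict,
                   seeds: dict | None = None, extra: dict | None = None) -> None:
    """JSON manifest of resolved parameters and seeds for exact reproduction."""
    from . import __version__

    payload = {
        "excitnet_version": __version__,
        "config": config.to_dict() if isinstance(config, ExperimentConfig) else config,
        "seeds": seeds or {},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_rate_profile(profile, path, K=None) -> None:
    """Rate-vs-rank TSV: rank_fraction, (K_i,) rate_hz."""
    cols = {"rank_fraction": profile.k_rank}
    if K is not None:
        cols["K_i"] = np.asarray(K, float)
    cols["rate_hz"] = profile.rate_hz
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def save_state(state, path) -> None:
    """Bit-exact JSON snapshot of a network state (V, g, spike/ref timers)."""
    payload = {
        "t": state.t,
        "V": state.V.tolist(),
        "g": state.g.tolist(),
        "y_steps": state.y_steps.tolist(),
        "ref_remaining": state.ref_remaining.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_state(path):
    from .records import NetworkState

    d = json.loads(Path(path).read_text())
    return NetworkState(
        t=float(d["t"]),
        V=np.array(d["V"], float),
        g=np.array(d["g"], float),
        y_steps=np.array(d["y_steps"], np.int64),
        ref_remaining=np.array(d["ref_remaining"], float),
    )
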
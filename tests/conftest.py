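"""Shared fixtures: canonical parameter sets and settled simulations.

The heavier simulations are session-scoped and shared between unit and
acceptance tests; everything is seeded, so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import excitnet as en

# canonical coupling-plane anchor points: (K_mean, Delta_K / K_mean) -> state
ANCHORS = {
    (2.0, 0.9): "I+D",
    (2.0, 0.2): "D+S",
    (3.0, 0.6): "D",
    (3.0, 0.1): "D+S",
    (12.0, 0.1): "S",
    (0.1, 0.0): "I",
}

ANCHOR_SEED = 1
# 10 s transient + 20 s measurement: settling into full synchrony can take
# >10 s near the mixed/synchronized boundary, and a 20-s window resolves
# per-neuron rates to 0.05 Hz — below the ~0.5 Hz/neuron slope of the
# flattest drifting continua, so plateau detection is not fooled by count
# quantization
ANCHOR_DURATION = 30000.0
ANCHOR_TRANSIENT = 10000.0
ANCHOR_MEASURE = 20000.0


@pytest.fixture(scope="session")
def params() -> en.NeuronParameters:
    return en.NeuronParameters()


@pytest.fixture(scope="session")
def anchor_records(params) -> dict[tuple[float, float], en.SpikeRecord]:
    """Settled 12-s spike records at the six anchor parameter points."""
    out = {}
    for (Kb, ratio) in ANCHORS:
        cc = en.CouplingConfig(N=100, K_mean=Kb, Delta_K=ratio * Kb)
        res = en.simulate(params, cc,
                          en.SimulationConfig(duration=ANCHOR_DURATION,
                                              seed=ANCHOR_SEED))
        out[(Kb, ratio)] = res.spikes
    return out


@pytest.fixture(scope="session")
def anchor_profiles(anchor_records):
    return {k: en.rates_from_spikes(r, ANCHOR_TRANSIENT, ANCHOR_MEASURE)
            for k, r in anchor_records.items()}


@pytest.fixture(scope="session")
def mixed_state_record(params) -> en.SpikeRecord:
    """Long run in the mixed drifting+synchronized state (K=2.0, dK/K=0.2).

    300 simulated seconds yield > 30k interspike intervals per drifting
    neuron — enough for the return-map dimension estimate.
    """
    cc = en.CouplingConfig(N=100, K_mean=2.0, Delta_K=0.4)
    res = en.simulate(params, cc,
                      en.SimulationConfig(duration=300000.0, seed=5))
    return res.spikes


@pytest.fixture(scope="session")
def mixed_state_drifting_neuron(mixed_state_record) -> int:
    """A mid-range drifting neuron of the mixed state (outside the plateau)."""
    profile = en.rates_from_spikes(mixed_state_record, 2000.0, 10000.0)
    label = en.classify_state(profile)
    assert label.label == "D+S"
    drifting = np.setdiff1d(np.where(profile.rate_hz >= 1.0)[0], label.cluster)
    return int(drifting[len(drifting) // 2])
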
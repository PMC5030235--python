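"""Interspike-interval regularity across states: the CV contrast.

Drifting neurons fire almost periodically when no synchronized cluster
exists, but become irregular in the mixed state, where the cluster's
periodic drive beats against their own (incommensurate) firing rate.
"""

import numpy as np

import excitnet as en

params = en.NeuronParameters()


def drifting_cv(K_mean, ratio):
    coupling = en.CouplingConfig(N=100, K_mean=K_mean, Delta_K=ratio * K_mean)
    res = en.simulate(params, coupling, en.SimulationConfig(duration=22000, seed=11))
    profile = en.rates_from_spikes(res.spikes, 2000, 20000)
    label = en.classify_state(profile)
    stats = en.isi_statistics(res.spikes)
    drifting = np.setdiff1d(np.where(profile.rate_hz >= 1.0)[0], label.cluster)
    cv = np.nanmean(stats.CV[drifting if len(drifting) else slice(None)])
    return label.label, cv


for K_mean, ratio in [(3.0, 0.6), (3.0, 0.1), (12.0, 0.1)]:
    label, cv = drifting_cv(K_mean, ratio)
    print(f"K_mean={K_mean:5.1f} dK/K={ratio:.1f}  state {label:4s}  "
          f"mean CV of non-plateau neurons = {cv:.4f}")

# Typical output: CV ~ 0.009 in the pure drifting state, ~ 0.055 for the
# drifting component of the mixed state (a >3x contrast), and ~ 0.001 in
# the fully synchronized state (delta-like ISI distribution).
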
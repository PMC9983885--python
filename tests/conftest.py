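"""Shared fixtures.

The population fixture lazily simulates spike trains per
(input level, SFA level, seed) and caches them for the whole session:
short-term depression is a pure post-processing of spike trains, so the
expensive Hodgkin-Huxley simulations are shared between STD conditions.
Population size 20 at 300 s keeps band-power orderings of the summed LFP
proxy well resolved while staying desk-scale.
"""

from types import SimpleNamespace

import pytest
from hypothesis import settings

import adaptspec as a

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")

N_NEURONS = 20
NET_DURATION = 300.0
NET_SEEDS = (0, 1, 2)
NET_BURN_IN = 10.0
FS_LFP = 200.0


@pytest.fixture(scope="session")
def population():
    """Lazy cache of population spike trains and LFP-proxy PSDs."""
    spike_cache = {}

    def spikes(input_level, sfa_level, seed):
        key = (input_level, sfa_level, seed)
        if key not in spike_cache:
            cfg = a.NetworkConfig(
                n_neurons=N_NEURONS, input_level=input_level,
                sfa_level=sfa_level, std_level="none",
                duration=NET_DURATION, base_seed=1000 * seed,
            )
            spike_cache[key] = a.simulate_population_spikes(cfg)
        return spike_cache[key]

    def psd(input_level, sfa_level, std_level, seed):
        t, lfp = a.lfp_from_spikes(
            spikes(input_level, sfa_level, seed), std_level, NET_DURATION, FS_LFP
        )
        return a.welch_psd(lfp[t >= NET_BURN_IN], FS_LFP)

    def broadband(input_level, sfa_level, std_level, seed):
        return a.band_power(psd(input_level, sfa_level, std_level, seed), 0.05, 100.0)

    return SimpleNamespace(
        spikes=spikes, psd=psd, broadband=broadband, seeds=NET_SEEDS
    )
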
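"""Noise-driven Hodgkin-Huxley neuron with spike-frequency adaptation.

Simulates the neuron at the Medium input condition with no, low and high
AHP conductance, printing the firing rates: adaptation is negative
feedback, so more AHP means fewer spikes.
"""

import adaptspec as a

p = a.HHParams()
noise = a.generate_filtered_noise(
    a.NoiseInput(sd=a.injected_sd(15.0), duration=30.0, seed=0)
)
for level in ("none", "low", "high"):
    _, train = a.simulate_neuron(p, a.AHPSet.from_level(level, p.G_Leak),
                                 noise, record_v=False)
    print(f"SFA {level:>4}: {a.firing_rate(train):5.2f} Hz "
          f"({len(train)} spikes in 30 s)")
print("Medium input is calibrated to ~10 Hz without adaptation; "
      "AHP currents progressively silence the neuron.")
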
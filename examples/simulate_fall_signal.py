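"""Simulate a six-phase fall signal and summarize its phases.

Builds the default forward-fall protocol (prefall steps, stumble/impact,
resting with hands on the ground, raising the upper body, kneeling rest,
standing up), simulates the lower-back triaxial acceleration at 100 Hz,
and prints the per-phase durations and per-axis extrema.
"""

from fallwarp import default_protocol, phase_summary, simulate_fall, write_signal_csv

protocol = default_protocol(seed=7)
signal, annotations = simulate_fall(protocol)

print(f"simulated {signal.n_samples} samples at {signal.sampling_rate_hz:g} Hz "
      f"({signal.n_samples / signal.sampling_rate_hz:.1f} s)")
print(phase_summary(signal, annotations).round(3).to_string(index=False))
write_signal_csv(signal, "simulated_fall.csv")
print("\nEach row is one fall phase: duration in seconds plus the min/max "
      "acceleration (g) per axis; z ~ 1 g in upright rest, the label-2 row "
      "carries the impact transient.")
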
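"""Systematic validation on synthetic quadcopter thrust profiles.

Generates constant and semi-sinusoidal thrust profiles, records each
through the simulated platform (structural modes, preload, noise, 2 mN
quantization), calibrates, filters both measurement and reference with
the same 30 Hz zero-phase Butterworth filter, and tabulates impulse
ratio, force ratio and cross-correlation delay over replicates.
"""

import dataclasses

from afplab import presets
from afplab.workflows import RunConfig, run_validation_experiment

# scaled-down run: 12 periods per sinusoidal profile, 10 replicates
profiles = tuple(
    dataclasses.replace(p, n_periods=12) for p in presets.VALIDATION_PROFILES
)
cfg = RunConfig(profiles=profiles, n_replicates=10, seed=42)
run = run_validation_experiment(cfg)

print(run.table.to_string(float_format=lambda x: f"{x:.4f}"))
print()
print("ratios of 1.000 within a few parts per thousand: the platform reads the")
print("true impulse and mean force to its quantization-limited accuracy; the")
print("delay (NaN for constant thrust: nothing to correlate) stays well inside")
print(f"the instrument's natural vibration period "
      f"({1e3 * presets.PLATFORM_MODES.natural_period:.1f} ms)")
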
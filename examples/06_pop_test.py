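"""Identifying the platform's natural frequency with a pop test.

Excites the simulated platform with five impulse events (balloon pops),
then reads the dominant structural resonance off the Welch spectrum of
the ringdown — the standard check that the instrument is stiff enough
for the force fluctuations of interest.
"""

from afplab import natural_frequency, pop_test, presets

rec = pop_test(presets.PLATFORM_MODES, presets.PLATFORM_SENSORS, n_pops=5, seed=3)
f_hat = natural_frequency(rec, band=(50.0, 300.0))

print(f"configured primary mode : {presets.PLATFORM_MODES.primary.natural_frequency:.0f} Hz")
print(f"estimated from pop test : {f_hat:.1f} Hz")
print(f"natural vibration period: {1e3 / f_hat:.1f} ms — the intrinsic response")
print("delay scale of the instrument, an order of magnitude above the ~1 ms")
print("acoustic transmission delay")
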
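"""Wingbeat-resolved weight support of a synthetic parrotlet flight.

Generates a 28 g bird hopping between perches at a 20 Hz wingbeat with
downstroke force peaking at twice body weight and near-zero upstroke
support, records it through the simulated platform, filters at 60 Hz and
reduces to per-stroke and per-wingbeat weight support.
"""

from afplab import presets
from afplab.workflows import RunConfig, run_flight_experiment

run = run_flight_experiment(RunConfig(seed=7))
s = run.summary

print("per-stroke weight support (vertical force / body weight):")
print(s.strokes.to_string(float_format=lambda x: f"{x:.3f}"))
print()
print("wingbeat averages (downstroke paired with its following upstroke):")
print(s.wingbeats.to_string(float_format=lambda x: f"{x:.3f}"))
print()
print(f"peak support {s.peak_support:.2f} (downstroke peaks near twice body weight);")
print("upstroke averages near zero: in this flight style the downstroke, not")
print("the upstroke, carries the body weight")
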
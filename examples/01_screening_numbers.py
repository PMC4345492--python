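"""Screening numbers: when does a wall-pressure platform work?

Computes the dimensionless numbers that justify reading an interior
unsteady force off the enclosure walls: the acoustic-compactness (AFP)
number, the sound transmission delay, the Reynolds number that makes wall
shear negligible, the laminar-shear bound itself, and the pressure
sensitivity of the load-cell array.
"""

from afplab import (
    acoustic_delay,
    afp_number,
    aperture_area_ratio,
    blasius_shear_force,
    presets,
    pressure_sensitivity,
    reynolds_number,
)

geom = presets.AFP_BOX
fluid = presets.AIR

n = afp_number(presets.AFP_LENGTH, presets.MAX_FORCE_FREQUENCY, fluid.c)
delay, frac = acoustic_delay(presets.AFP_LENGTH, fluid.c, presets.MAX_FORCE_FREQUENCY)
re = reynolds_number(presets.NEAR_WALL_SPEED, geom.Lz, fluid)
shear = blasius_shear_force(presets.NEAR_WALL_SPEED, geom.Lz, geom.Lx, presets.AIR_25C)
sens = pressure_sensitivity(presets.PLATFORM_SENSORS.resolution, geom)

print(f"AFP number (f L / c)        : {n:.4f}   (<< 1: enclosure is acoustically compact)")
print(f"acoustic delay L/c          : {delay*1e3:.2f} ms ({100*frac:.1f}% of the forcing period)")
print(f"Reynolds number U L / nu    : {re:.0f}   (>> 1: wall shear negligible vs pressure)")
print(f"laminar shear bound         : {shear*1e3:.2f} mN on one wall at U = "
      f"{presets.NEAR_WALL_SPEED} m/s")
print(f"pressure sensitivity        : {sens*1e3:.1f} mPa (2 mN resolution / horizontal area)")
for d in (0.100, 0.175, 0.250):
    print(f"front-wall hole d = {d:.3f} m : area ratio {aperture_area_ratio(d, geom):.3f}")
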
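# Methods

`afplab` is a virtual aerodynamic force platform (AFP): a simulation and
analysis pipeline for the measurement principle in which a rigid,
load-cell-instrumented enclosure mechanically integrates the wall pressure
produced by an object or animal generating unsteady fluid force inside it,
so that the net force can be read from the ground reaction.  This note
documents the models, parameters, numerical choices and limitations.

## The control-volume principle

For a closed control surface S with outward normal n̂ around an
incompressible fluid volume containing a force source, the momentum
integral of the Navier–Stokes equations reduces, after applying the
no-slip/no-flow condition on rigid walls, to a surface integral of
pressure and shear:

    F(t) = −∮_S [ p(t) n̂ − τ̄ · n̂ ] dS .

Two dimensionless numbers decide when the walls can stand in for this
integral in real time:

- **AFP number** `AFP_n = f L / c` — the enclosure scale `L` over the
  acoustic wavelength at the highest force-fluctuation frequency `f`.
  When `AFP_n ≪ 1` the enclosure is acoustically compact: pressure
  fluctuations reach the walls quasi-instantaneously, the transmission
  delay `L/c` being `AFP_n` of a forcing period.
- **Reynolds number** `Re = U L / ν` — when `Re ≫ 1` the wall shear
  contribution is negligible against pressure; the package bounds it with
  the laminar flat-plate (Blasius) friction drag
  `C_f = 1.328 Re_L^{−1/2}`, which for the default platform and a
  near-wall speed of 0.95 m s⁻¹ is about 1 mN — below the 2 mN load-cell
  resolution.

## Incompressible wall-pressure solver

The paper-scale verification that the wall integral recovers an interior
force is implemented as a pressure Poisson problem: a concentrated force
`F` applied by the object at interior point `x₀` exerts the reaction `−F`
on the fluid, and taking the divergence of the momentum equation in a
rigid box with `∂p/∂n = 0` on all six walls gives

    ∇²p = ∇·(−F g(x − x₀)) ,

where `g` is a narrow isotropic Gaussian regularizing the point force.
The solution is a triple cosine eigenfunction expansion (the natural
Neumann basis for a box), truncated at `n_modes` per axis; the Gaussian
factor makes the modal spectrum decay super-exponentially, so the default
48 modes per axis are converged far below quadrature error.  Without
regularization the series for the wall force converges only like a
square-wave Fourier series (error ∝ 1/n_modes); with it, the recovered
force is exact for any source width whose mass stays inside the box, which
is why the default width adapts to `min(min(L)/12, d_wall/4)` near walls.
The mirror (even) extension of the Gaussian across the walls makes the
modal filter exact even for near-wall sources.

Wall grids default to 64×64 Simpson-ready panels per wall;
`integrate_wall_force` computes `−∮ p n̂ dS` by composite Simpson
quadrature, subtracting any aperture disc by polar Gauss–Legendre
quadrature of the bilinearly interpolated field.  At the defaults, 20
randomized interior forces are recovered with relative error below 10⁻⁴
(requirement: 10⁻³).

**Gauge.** The Neumann problem defines pressure up to a constant; the
solver fixes a zero volume mean.  A constant integrates to zero force on a
closed surface, so the gauge is irrelevant there; with an aperture the
constant is shifted so the mean pressure on the aperture rim is zero (hole
open to atmosphere).  The independent method-of-images oracle in the test
suite (free-space regularized dipoles summed over ≥ 5 mirror shells, force
components sign-flipped per reflection) agrees with the spectral wall
field to ~0.01% RMS after removing the arbitrary constant.

**Aperture insensitivity.** A hole in a vertical wall cannot change the
recovered *vertical* force in this inviscid model, exactly: that wall's
outward normal has zero vertical component.  This is the mechanism behind
the observed insensitivity of measurement accuracy to front-panel holes of
up to 22.3% area ratio.

## Compressible transmission-delay demonstration

Replacing the Poisson closure with the linear-acoustics wave equation,
each axis-aligned `(0,0,m)` cosine mode line becomes a second-order
resonator at `ω_m = c m π / L` driven by the forcing waveform; only these
mode lines carry net wall force.  Modal damping (default ζ = 10⁻³,
configurable) bounds resonant transients, which would otherwise never
settle.  A physically important subtlety: in a near-lossless cavity the
standing-wave *steady state* carries essentially no phase lag — the
acoustic delay lives in the start-up transient, where the wall force stays
zero until the wavefront arrives (~`L/(2c)` from a centered source) and
then reverberates onto the applied force.  The demo therefore estimates
the delay by per-lag-normalized cross-correlation over the first acoustic
round trip (`2 L / c`); longer windows are progressively dominated by the
phase-locked reverberant response and bias the estimate toward zero.  At
the default platform extremes (L = 0.41 m, f = 18 Hz, c = 340 m s⁻¹) the
measured delay is ≈ 0.44 ms, a fraction ≈ 0.8% of the forcing period —
below, and of the order of, the 2.2% compactness bound given by the AFP
number, which is the quantity usually quoted as "the" phase delay.  Across
a sweep `AFP_n ∈ [10⁻³, 10⁻¹]` the measured fraction grows monotonically
with `AFP_n` and vanishes in the incompressible limit.  Forcing within 1%
of an acoustic mode is flagged, not rejected.

## Instrument model

The platform is modeled as a participation-weighted sum of second-order
resonators with unity DC gain: a dominant 132 Hz vertical mode with a
weakly coupled small-amplitude 105 Hz mode (5% participation), following
the published modal description; the validation reference beam is a single
138 Hz mode.  Damping ratios are not published; ζ = 0.03 per mode is
typical of stiff balsa sandwich construction, is configurable, and only
enters ringdown comparisons made against the same parameterized closed
form.  The recording chain is: modal filtering (continuous-time `lsim` on
an internal grid of at least 10× the highest mode frequency) → equal split
over the statically determinate, equally preloaded channels (3 platform /
2 beam; preload 1.79 kg × g for the platform) → inverse calibration gain
(raw sensor units; the published linear coefficients are 0.989 platform,
0.997 beam) → seeded Gaussian noise (default 1 resolution step RMS) →
mid-tread quantization at 2 mN → sampling at 1 ms.  `apply_calibration`
multiplies raw channels by the coefficient once (double application is a
state error).  Only the vertical axis is simulated; the published
instrument resolves vertical force, and 6-axis generalization is out of
scope.

## Signal pipeline

- **Filtering:** 4th-order low-pass Butterworth, 30 Hz for validation
  runs, 60 Hz for flight runs (chosen above the 20 Hz wingbeat).
  Zero-phase (forward–backward) application is the default: both
  measurement and reference receive the identical filter, so the
  cross-correlation delay isolates the instrument's structural dynamics
  rather than filter group delay; single-pass mode is retained for
  sensitivity checks.  Whether the original analysis was zero-phase is not
  stated; this is the package's choice and is documented as such.
- **Validation metrics:** total impulse ratio (trapezoidal), mean-force
  ratio, and cross-correlation delay with parabolic sub-sample
  interpolation, positive when the platform lags.  For constant thrust
  the delay is NaN (nothing to correlate), mirroring the dash in the
  published validation table.
- **Natural frequency:** Welch periodogram of the pop-test net force
  (segments average across pops), band-restricted peak with parabolic
  log-power refinement; recovers the configured 132 Hz mode to well
  within the ~1 Hz spectral resolution.
- **Net acceleration:** `a(t) = (F(t) − W)/m`.
- **Weight support:** per-stroke trapezoidal mean of `F/W`; a wingbeat
  pairs each downstroke with its following upstroke, duration-weighted.
  The handling of a trailing unpaired stroke is not fully specified by
  the stroke-direction convention, so it is an explicit option
  (`last_stroke="separate"` reports it as an incomplete wingbeat,
  `"drop"` omits it).  Take-off/landing bounds are inputs (from video or
  the generator); no force-based flight detection is attempted.

## Synthetic data

The generators define the study conditions; they are seed-deterministic
and every trace carries its generating spec for parameter-recovery tests.

- **Thrust profiles:** constant, or semi-sinusoidal — a mean-offset
  sinusoid clipped at zero thrust (rotors cannot pull; clipping rarely
  engages at the default 0.5 N modulation about 1 N mean) — at the
  validation presets 0.125/0.25/0.5 Hz, 84 periods; plus a
  "hand-controlled" profile modeled as a seeded random walk band-limited
  below 2 Hz.
- **Bird flights:** a 28 g parrotlet at 20 Hz wingbeat, perches 0.28 m
  apart.  Downstroke vertical force is a half-sine peaking at 2× body
  weight (the trapezoid alternative was considered and rejected for
  smoothness); the upstroke holds a small constant support (default 0.05
  W), so the analytic wingbeat mean is `d·peak·2/π + (1−d)·up` with
  downstroke fraction d = 0.5.  Cycle-to-cycle amplitude jitter is ±5%.
  Take-off leg push and landing deceleration are raised-cosine impulses
  just outside the flight bounds (style differences between individuals
  are not modeled).  Default flight length is 8 wingbeats (0.4 s) — a
  documented guess for a sub-second perch-to-perch hop, configurable.
  The within-stroke waveform is a stand-in: real per-stroke force shapes
  are known only qualitatively and are never used as reproduction
  targets.
- **Pop impulses:** raised-cosine pulses (single-pulse impulse
  `amplitude·width/2`), default 2 ms width / 5 N amplitude — short enough
  to excite the 132 Hz mode broadband — with seeded timing jitter.

## What the synthetic experiments do and do not show

The end-to-end validation (generate → record → calibrate → filter →
compare) yields impulse and force ratios of 1.000 ± 0.005 over 10
replicates and delays well inside the instrument's natural vibration
period (7.6 ms at 132 Hz).  The published hardware experiment showed
ratios of ~1.01–1.02; that bias is attributed to real, un-instrumented
shear on the acrylic panel, which this inviscid virtual instrument does
not model — so exact unity here demonstrates pipeline correctness, not a
reproduction of the hardware bias.  Likewise the in-vivo wingbeat-support
values of real birds are not reproduction targets: the flight pipeline is
validated by recovering the generator's configured ground truth
(downstroke-only support, peak ≈ 2 W within filter-attenuation and modal
ringing bounds) through the full measurement chain.

## Parameters and problem sizes

| parameter | default | note |
|---|---|---|
| box inner dimensions | 0.525 × 0.452 × 0.420 m (W×D×H) | published inner dimensions |
| fluid | ρ = 1.204, ν = 1.48e−5, c = 340 (SI) | ν chosen consistent with the published Re ≈ 27 000 at 0.42 m height; the 25 °C value (1.562e−5) is available as `AIR_25C` for shear estimates |
| spectral solver | 48 modes/axis, 64×64 grids | documented convergence in the test suite |
| source width | min(min L/12, d_wall/4) | keeps source mass inside the box |
| acoustic damping | ζ = 10⁻³ | bounds resonant transients |
| structural damping | ζ = 0.03/mode | unpublished; typical for balsa sandwich |
| mode coupling | 5% participation at 105 Hz | realizes "weakly coupled, small-amplitude" |
| sensor | 2 mN, 1 ms, noise 2 mN RMS | resolution-limited accuracy |
| validation runs | 12 periods/profile, 10 replicates | scaled-down analog of the 84-period protocol; the statistics are quantization/noise-limited and insensitive to record length |

## Known limitations

- Inviscid, quiescent-bulk idealization: no wake, vorticity or
  convective momentum transport; the bulk velocity field is analytically
  eliminated on the control surface and never represented.  Shear enters
  only as the scalar Blasius bound.
- The original analytical verification of the principle is not described
  in detail anywhere; the Poisson/dipole construction here is this
  package's own, validated internally (momentum conservation, image-series
  oracle) rather than against that unpublished derivation.
- Only vertical force is instrumented; moments and horizontal components
  are generated but not analyzed.
- The quantitative "+0.8% of total force" shear estimate for the hardware
  cannot be reproduced because the reference total force it was normalized
  by is not published; the package reports the shear force in millinewtons
  instead.
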
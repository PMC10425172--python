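# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `odorscape`, in the order the pipeline runs.

## Sensor calibration

Metal-oxide gas sensors report a raw dimensionless signal; a photo-ionization
detector (PID) downstream of the chamber provides the absolute reference.
The response law is exponential,

    ppm(t) = A · exp(B · raw(t − τ)),

with scale `A` (ppm), sensitivity `B` (per raw unit), and transport delay `τ`
(s) between the sensor location and the PID.

**Delay estimation.** Both series are linearly resampled to the coarser of
the two nominal rates (odor sensors 1 Hz, PID up to 13 Hz) and
cross-correlated using the Pearson correlation of the overlapping segments at
each integer lag, i.e. with per-overlap means and variances. The usual
global-mean-subtracted correlation is biased toward zero lag for slowly
varying delivery waveforms (a 500 s triangle wave moves the apparent peak
from 5 s to under 2 s); the per-lag normalization removes that bias. The
search window is a quarter of the common record; the discrete peak is refined
by parabolic interpolation, and a peak on the window edge raises an
unreliable-delay warning. The estimator is antisymmetric under argument
swap.

**Fit.** Because the law is log-linear, `(A, B)` are obtained by linear
regression of `log(reference)` on delay-aligned raw readings, with the
reference clipped at a 1e-3 ppm floor to stabilize the logs; the reported
`fit_mse` is computed in linear (ppm²) space. A constant reference is
flagged degenerate with `A` = mean reference and `B` = 0. The PID
voltage→ppm gain is a per-instrument configuration constant (two dynamic
ranges exist, 0–200 and 0–1000 ppm) and is never inferred from data.
Curves are fitted per sensor; no pooling. Stability of a curve is validated
by refitting on a replicate recording and reporting the maximum fractional
change of predicted concentration over the common raw range, with a 10%
pass criterion.

## Plume model

With laminar carrier flow `v` (≈0.5 cm/s) down the x axis and molecular
diffusivity `D` (≈0.08 cm²/s for butanone in air), the steady concentration
obeys the boundary-layer form `v ∂C/∂x = D ∂²C/∂y²`: streamwise transport is
convective (Péclet ≈ 80 over the ~13 cm arena), spanwise transport
diffusive. Downstream distance plays the role of time, so a narrow inlet
source relaxes into Gaussian cross-sections with variance σ² = 2Dx/v.

**Solver.** The equation is marched downstream explicitly with sub-stepping
(diffusion number ≤ 0.45), a top-hat inlet source one port spacing wide
(chamber width / 15 inlets = 1 cm) and no-flux side walls; the spanwise
integral is conserved along x. The resolution guard requires the spanwise
spacing to resolve a quarter of the smaller of the local plume σ and the
source footprint.

**Diffusivity fit.** `fit_plume` minimizes the MSE between a sensor
snapshot and the closed-form solution for a sustained top-hat source in an
unbounded span — the heat-kernel convolution, `C = A/2·[erf((y−y₀+w/2)/s) −
erf((y−y₀−w/2)/s)]` with `s² = 4Dx/v` — with amplitude and source position
as nuisance parameters and `D` free. The erf form rather than a bare
Gaussian matters at small `D`, where the 1 cm footprint contributes a
non-negligible share of the cross-section variance; with it, generative `D`
over {0.02, 0.05, 0.08, 0.15} cm²/s is recovered within 10% at 2% sensor
noise. A near-flat MSE profile in `D` raises an unidentifiability warning.

**Diagnostics and droplet release.** Reynolds (`v·depth/ν`, ν = 0.15 cm²/s
for air) and Péclet numbers use the bulk velocity `flow rate /
cross-section`. The sealed-chamber droplet release is solved spectrally
(cosine series per axis, reflecting walls, depth-averaged); mass is
conserved exactly and the long-time limit is the ideal-gas equilibrium
concentration `1e6 · n·Vm(T) / V`.

## Odor–agar dynamics

Airborne butanone partitions into agar. The airborne field `C` couples to a
depth-integrated agar reservoir `A` (non-zero only on the agar mask) via

    ∂C/∂t = −v ∂C/∂x + D ∇²C − w ∂A/∂t,
    ∂A/∂t = ka C (1 − A/M) − kd A,

with association/dissociation rates `ka`, `kd`, capacity `M`, and coupling
weight `w` (`w = 0` ⇔ no agar). The defaults `ka = 0.05 /s`, `kd = 0.001 /s`,
`M = 2× target Co`, `w = 1` are not measured quantities; they place the
system in the strongly absorbing regime (`ka ≫ kd`, `Co < M`) that
reproduces the observed phenomenology — downstream depression after agar
introduction, slow unassisted equilibration, absorption/re-emission in
pulse-chase — and only regime-level behavior is asserted about them. The
agar has no lateral in-gel transport term, matching the model's
phenomenological character.

**Quasi-equilibrium identity.** At steady state `∂A/∂t = 0`, so the `C`
equation reduces to the agar-free equation with the same boundary
conditions: the with-agar airborne landscape equals the no-agar landscape.
This is the identity that lets boundary monitoring certify the interior
field. It is verified three ways: analytically for the point model
(`C* = Co`, `A* = ka·Co·M/(ka·Co + kd·M)`), numerically for the PDE (mean
fractional difference between pre-equilibrated with-agar and no-agar steady
fields below 10%; measured ≈0.05% on the 2 mm grid), and at the boundary
profiles (downstream spanwise profile within 10% pointwise where
significant).

**Numerics.** First-order upwind convection, explicit centered diffusion,
and a local reaction sub-update share one explicit step. The step obeys the
combined bound `dt ≤ 0.8 / (v/dx + 2D(1/dx² + 1/dy²))` — convection and
diffusion Courant fractions must sum below one, which is stricter than
bounding each separately — and `dt ≤ 1/(10(ka+kd))`. Boundaries: Dirichlet
inlet profile at x=0 from the source schedule, zero-gradient (convective)
outflow at x=L, no-flux side walls. Grid default 2 mm. Step-wise mass
accounting (`d/dt(ΣC + wΣA)` vs boundary fluxes, including the inlet
diffusive exchange) closes to <0.5% cumulatively.

**Pre-equilibration protocol.** Loading the gel at the target concentration
takes far longer than an experiment when `ka ≫ kd`, so the protocol runs the
source at a boosted concentration (above `M`), monitors the mean
concentration at downstream probe points every 10 s (configurable), switches
to the target source at the first crossing of the no-agar steady level, and
holds. Paired simulations confirm the protocol settles the boundary within
5% of target strictly sooner than a constant source, and the switch time is
non-increasing in the boost factor.

## Field reconstruction

The sensor array geometry is generated deterministically: per bar, 16 odor
sensors in two columns 1 cm apart, 1.5 cm within-column spacing, staggered
by 0.75 cm (0.75 cm effective spanwise resolution); 2 cm bar pitch so
adjacent-bar columns are 1 cm apart; 7 bars = 112 odor sensors in a
triangular grid. Humidity sensors are carried in layouts but excluded from
concentration interpolation.

Snapshots are interpolated with a thin-plate smoothing spline
(`scipy` RBF) with coordinates scaled by the median nearest-neighbour
sensor spacing (~1 cm), which ties the smoothing length to the array
density; the penalty defaults to a near-interpolating 1e-3 and zero gives
exact interpolation. Negative interpolant values are clipped at zero with a
logged count, and grid nodes outside the sensor convex hull are flagged
extrapolated. Gradients use centered finite differences after a σ = 0.5 cm
Gaussian pre-smoothing (one-sided at edges; exact for linear fields away
from the kernel's reach). 1-D boundary profiles are summarized by
least-squares Gaussian fits (peak, center, σ, optional baseline), with a
degenerate flag for flat profiles.

## Navigation analysis

Conventions: angles in degrees in (−180°, 180°], CCW positive viewed from
above; bearing θ is the signed angle from the local gradient direction to
the velocity direction, so 0° = up-gradient. Bearings are undefined (and
excluded from conditioned statistics) where |∇C| is below 1% of its field
maximum or the speed is below 0.01 mm/s. Trajectories are in mm; fields in
cm; `GradientContext` handles the conversion.

* **Smoothing** — per-coordinate Savitzky–Golay, third-order polynomial over
  a 0.5 s window (7 samples at 14 Hz), endpoints from the edge-window
  polynomials. The 7-point cubic window has white-noise variance gain 1/3,
  i.e. ~42% RMS noise reduction; tracks shorter than a window are returned
  unsmoothed with a flag.
* **Filtering** — keep tracks with duration > 60 s, net displacement > 3 mm,
  and starting concentration not above 70% of the field maximum (animals
  starting near the peak have already chemotaxed). All strict inequalities.
* **Turns (pirouettes)** — angle change between displacement vectors
  spanning consecutive 1 s windows; candidates above 60° are merged within a
  1 s refractory period keeping the instant of maximum change, so slow
  continuous turns are not double-counted. Turn-rate denominators include
  all occupancy time (bout durations are not excluded).
* **Turn rate vs bearing** — folded |θ|, 30° bins; rate = counts/occupancy
  with counting error √N/T. Empty bins are NaN, not zero.
* **Curvature** — the path is resampled at 1 mm arc length; curvature is the
  signed angle between successive 1 mm displacements (deg/mm). Per-step
  angle changes at or above the 60° turn threshold are excluded by default:
  weathervaning is a run property, and sharp-turn events — sign-symmetric
  but ±~120° in a single step — would dominate the sample variance without
  shifting the mean. Quadrant classes {|θ|<45°, 45°≤|θ|<135°, |θ|≥135°};
  within classes the sign is re-oriented so positive = turning toward the
  gradient (toward-gradient curvature is −sign(θ)·κ). Pairwise class
  comparisons use two-sample Kolmogorov–Smirnov tests; classes under 50
  samples carry a low-power flag. With these conventions the signed
  mean-curvature-vs-bearing curve of a weathervaning population is
  ≈ −g·sin θ.
* **Drift velocity** — V·cos θ binned by |∇C| (quantile bins); per bin the
  mean, quartiles, a one-sample t-test against zero, and two-sample t and KS
  tests against the lowest-gradient bin. Test p-values are reported raw;
  significance flags use α = 0.001.
* **Larva statistics** — the same centroid-based 60°/1 s turn operator
  (posture-based head-cast detection would require body-shape data, which is
  out of scope — a documented deviation from posture-based larva pipelines);
  turn rate per signed bearing quadrant {0°, +90°, −90°, 180°} and mean
  wrapped heading change per pre-turn quadrant, with circular means so that
  {+179°, −179°} averages to ±180°.

## Synthetic data

The agent model is a deliberately simple construction — real animals are
described by the statistics these agents reproduce, not by this generative
law. Per step: heading drifts toward the gradient at `g·sin|θ|` deg/mm
(weathervaning), plus Gaussian heading noise (deg/√s); a turn fires with
probability `λ0(1 − b·cos θ)·dt` (biased random walk, `b ≤ 1` keeps the rate
non-negative), drawing a magnitude from a normal kernel (mode 120° for
worms, 60° for larvae) whose sign is random unless `turn_correction > 0`,
which biases it toward the gradient (the larva corrective-reorientation
signature). Positions advance at constant speed with reflecting walls;
output at 14 Hz. Defaults: worms 0.1 mm/s, λ0 = 0.03 /s, noise 2 deg/√s;
larvae 3 mm/s, λ0 = 0.05 /s, noise 8 deg/√s — speeds at the two organisms'
scales, rates giving realistic turn counts (hundreds of turns per
~7 animal-hours at larva scale).

What the generator does not emulate: body posture and undulation, reversals
vs omega-turn taxonomy, sensory adaptation or odor-history dependence, and
speed modulation. Passing recovery tests therefore show that the analysis
pipeline is unbiased for run-and-turn kinematics at these speeds and rates,
not that real animals follow this law.

Synthetic recordings push the true ppm at each sensor position through the
inverse calibration law with multiplicative noise; the reference series is
the spatial-mean ppm delayed by the transport time. Calibration recordings
use a spatially uniform field modulated by a 500 s triangle wave (the
instrument's calibration waveform), which makes the zero-noise round trip
(synthesize → fit) recover the true curves to high precision.

## Problem sizes and tolerances

The default test suite runs the spatial PDE on 2–5 mm grids and the
acceptance simulation on the 2 mm grid of a 15 × 17 cm chamber; behavioral
recovery uses 200 agents × 20 min at 14 Hz (the scale at which binned
estimators have ≤ a few percent standard errors). Parameter-recovery
tolerances (10% for D, 20% for (λ0, b, g), 5% for calibration constants)
reflect the residual estimator bias plus sampling noise at those sizes, and
were chosen alongside the generator settings. Optimizers use `scipy`
least-squares with log-parameterized positive quantities; ties in turn
merging resolve to the earliest instant of maximum |angle change|.

## Known limitations

* The PDE solver is first-order in the convection term; the w=0 steady
  state agrees with the marching closed form to ~0.7% RMS at 2 mm, not to
  machine precision.
* The pre-equilibration switch criterion is a single threshold crossing of
  the monitored mean; with strong boosts the crossing happens before the gel
  is loaded and the subsequent hold does the remaining loading. This matches
  the instrument protocol (monitor, switch, hold) but means "switch time" is
  not "time to equilibrium".
* Delay estimation assumes a single dominant transport delay; distributed
  lags (sensor response kinetics) fold into the exponential fit rather than
  the delay.
* The larva turn operator is centroid-based; head-cast-resolved statistics
  are out of scope.
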
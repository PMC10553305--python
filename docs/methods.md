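# Methods

## Encounter kinetics

The package's core is the ballistic encounter-rate kernel for a searcher of
encounter radius *R* moving at constant speed *y* among targets of density
*N* moving at constant speed *x*, both with uniformly random directions
(Gerritsen–Strickler):

    C_GS = (π R² N / 6) · [ (x + y)³ − |x − y|³ ] / (x y)

The kernel assumes straight-line (ballistic) motion on the scale of an
encounter, uncorrelated directions, and a hard perception sphere: a target
is "encountered" the moment its distance from the searcher first drops below
*R*. No capture, handling or post-encounter behaviour is modelled — the
output is exposure, not ingestion.

The formula's denominator is singular when either speed vanishes, which is
precisely the use case here: microplastics are treated as passive (*x* = 0).
`gs_rate` therefore switches to the analytic limit **π R² N max(x, y)**
whenever min(x, y) ≤ 10⁻¹² m s⁻¹. The limit is exact (the bracket tends to
6·max(x, y)) and the published chaetognath and luciferid rates confirm it is
what the swept-cylinder numbers represent; continuity across the switch is
tested to 10⁻⁹ relative. Both speeds zero is a degenerate input (no relative
motion) and raises an error rather than returning 0, to surface
configuration mistakes.

Turbulence enters through the Rothschild–Osborn substitution: each agent's
speed *v* is replaced by the effective speed √(v² + w²), with *w* the RMS
small-scale turbulent velocity. The substitution is itself an approximation:
if one emulates turbulence physically by vector-adding an independent
isotropic velocity of magnitude *w* to each agent, the exact mean relative
speed differs from the effective-speed value by ~2 % at the parameter ranges
used here. The Monte-Carlo oracle (below) quantifies this; the package
implements the substitution as stated because it is the model under study.

The RO/GS ratio (`turbulence_multiplier`) is independent of *R* and *N*
(both cancel), equals 1 at *w* = 0 and grows as *w*/y grows — slow swimmers
gain the most from turbulence.

### Taxon parameters

| taxon       | speed y (m s⁻¹) | radius R (m) |
|-------------|-----------------|--------------|
| copepod     | 0.062           | 4.0 × 10⁻⁴   |
| chaetognath | 0.04            | 0.02         |
| luciferid   | 0.016           | 0.02         |

The copepod speed deserves a note. The literature value cited for
*Acartia*-type copepods is 6.2 mm s⁻¹, but every published copepod result
this package reproduces (surface rates 1.5 and 0.2 particles ind⁻¹ h⁻¹,
multipliers 1.2 and 1.3) requires 6.2 **cm** s⁻¹; with 6.2 mm s⁻¹ the rates
are exactly ten-fold smaller and the June multiplier would be ≈ 6.5 rather
than 1.2. The registry default is therefore 0.062 m s⁻¹, with the literal
0.0062 m s⁻¹ available via `taxon_registry(copepod_speed_as_printed=True)`.
The discrepancy is documented rather than silently patched.

### Known discrepancy in the luciferid October multiplier

At *y* = 0.016, *x* = 0, *w* = 0.04 m s⁻¹ the RO/GS ratio evaluates to
3.466 (verified both by the closed form and by direct Monte-Carlo averaging
of |v_rel| over random directions). The study reports 3.3 for this case; a
ratio of 3.3 would correspond to *w* ≈ 0.038 m s⁻¹ rather than the printed
(rounded) 0.04. Since the surface turbulent velocities behind the original
figures are only known to two decimals, the package uses the printed values
and reports the honestly computed 3.466. All five other multipliers (1.181,
1.400, 2.676, 1.307, 1.650) round to the published values.

## Turbulence closure

The original turbulence computation is not fully specified (its defining
formulas live in prior literature); the package implements a deliberately
simple, calibrated closure:

* **surface velocity** w₀ = α_w · U, with α_w = 0.036 (dimensionless) so
  that the two seasonal winds (0.80, 1.12 m s⁻¹) map to w₀ ≈ 0.03 and
  0.04 m s⁻¹ after rounding to two decimals;
* **depth decay** w(z) = w₀ · exp(−z/λ), λ = 0.25 m, so w at the 1.5 m
  lagoon bottom is e⁻⁶ ≈ 0.25 % of its surface value ("almost zero");
* **energy** k = w² (m² s⁻²), reading the RMS relation w = √k literally
  (the isotropic alternative w = √(2k/3) would only relabel k and does not
  touch encounter rates, which consume w directly);
* **dissipation** ε = w³/l_mix with l_mix = 0.27 m, a mixing-length scaling
  that is dimensionally exact (m² s⁻³) and puts the June surface ε at
  1 × 10⁻⁴ m² s⁻³.

Because this closure is calibrated rather than transcribed, every scenario
also accepts an explicit `w0` override (defaults 0.03 June / 0.04 October),
which the bundled scenarios use; encounter-rate results therefore do not
depend on α_w at all. The published depth extents of the 10⁻⁴ dissipation
band (0–20 cm June, 0–30 cm October) cannot be matched simultaneously with
the surface values under any single-exponential profile and are not asserted.

The depth grid is 0 to 1.5 m inclusive at 0.01 m steps, positive downward.

## Bootstrap

The per-station concentration sets are small (n = 10 and 7), so sampling
uncertainty in the seasonal mean is propagated by a classical bootstrap of
the mean: each of `n_reps` (default 1000) repetitions draws a full-size
resample with replacement, takes its mean concentration, converts to density
(× 1000 L m⁻³) and applies the rate function; the reported SD is the
population SD (ddof = 0) over the repetition set. A `mode="single"` variant
draws one station per repetition instead — for rates linear in N the two
modes share the same expectation and differ only in spread. All randomness
flows from a single integer seed through `numpy.random.default_rng`, and
results are bitwise reproducible.

Within one profile fit, a single resample sequence is shared across all
depths. Depth variation of the turbulent profile then reflects w(z) only,
the RO/GS ratio at each depth is free of resampling noise, and profiles are
smooth; `redraw_per_depth=True` gives independent draws per depth instead.

## Synthetic station data

Only summary statistics of the original survey were published. The generator
draws from a truncated normal (alternatives: moment-matched scaled beta, or
integer-uniform), affine-adjusts the draw to hit the target mean and SD
exactly, clips to the requested range, and rejects-and-retries (≤ 1000
attempts) until the clipped sample mean is within 5 % and the SD within
15 % of target. Requests whose SD exceeds the Bhatia–Davis bound for the
range and mean fail immediately with a diagnostic. The two packaged fixtures
(June: 10 stations, sample mean 13.70, SD 6.87, range [7.0, 25.9]; October:
7 stations, mean 2.0, SD 1.70, range [0.26, 5.02]) were generated once from
fixed seeds and are synthetic stand-ins for the unpublished measurements.

What passing tests on these fixtures show is that the *pipeline* reproduces
the published rates given concentration sets with the published summaries;
they cannot show anything about spatial structure, detection limits or
seasonal dynamics of the real survey, and bootstrap SDs depend on the
(unknown) shape of the real station distribution, so SD bands are checked
only for invariants (positivity, scale equivariance), never against the
published figures.

## Monte-Carlo oracle

`simulate_encounters` places Poisson(N·L³) particles uniformly in a periodic
box of side L, gives every agent a ballistic velocity (plus an independent
isotropic component of magnitude w when emulating turbulence), and counts
entries of particles into the searcher's moving sphere by solving, in the
searcher's rest frame, the quadratic |r₀ + v_rel·t| = R for every particle
and every periodic image reachable within the trial duration — an exact
continuous-time treatment with no time-step artifacts. Re-entries count
again, matching the rate semantics of the closed forms. Agreement is judged
against three standard errors of the trial-mean rate; with the default
problem sizes (box 0.5 m, 15–30 s trials, 30–40 trials) each comparison
resolves the analytic rate to a few percent in roughly a second.

## Problem sizes and numerical choices

Default test and acceptance runs use 200–1000 bootstrap repetitions, the
151-point depth grid, and the oracle sizes above; the full study
(12 profiles × 1000 repetitions) completes in a few seconds. Reported
summary tables round rates ≥ 100 to three significant figures, rates < 10
to one decimal and multipliers to one decimal, matching conventional
field-report precision. Profile CSVs are written at 12 significant digits
and round-trip exactly at that precision; manifests carry seeds, parameter
values and package version, and omit timestamps by default so identical
runs are byte-identical.

## Limitations

Ballistic, behaviourally blind kinetics; no capture probability, handling
time or functional response; no particle buoyancy, size spectrum or polymer
composition; depth-invariant particle concentration; a calibrated
rather than derived turbulence closure with no stratification, waves or
tides. The numbers are exposure ceilings for the first step of the
predation cycle, not ingestion estimates.
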
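# zooencounter

Encounter rates between zooplankton and microplastic particles in a shallow
tropical estuary, under calm and wind-induced turbulent conditions.

Microplastics suspended in the water column behave like passive "alleged
prey": before a zooplankter can ingest a particle or get entangled in it, it
has to *encounter* it. This package estimates how often that first step
happens, per individual and per hour, for three common estuarine taxa with
very different swimming speeds and perception distances — calanoid copepods
(*Acartia tonsa*-like), chaetognaths (*Parasagitta friderici*-like) and
luciferid shrimps (*Belzebub faxoni*-like) — in two seasons that differ in
both microplastic load and wind forcing. It is aimed at plankton ecologists
and ecotoxicologists who want exposure estimates from concentration surveys.

## The models

Calm water uses the Gerritsen–Strickler ballistic encounter kernel. For a
searcher of encounter radius *R* (m) and speed *y* (m s⁻¹) among targets of
number density *N* (m⁻³) moving at speed *x*:

    C_GS = (π R² N / 6) · [ (x + y)³ − |x − y|³ ] / (x y)

Microplastics drift passively (*x* = 0), where the formula's analytic limit
is the swept-cylinder clearance rate **C = π R² N y**. Wind-induced
small-scale turbulence is added with the Rothschild–Osborn substitution:
each speed *v* is replaced by the effective speed √(v² + w²), where *w* is
the RMS turbulent velocity. *w* decays roughly exponentially with depth in a
1.5 m-deep lagoon, so turbulent encounter rates converge to the calm-water
rates near the bottom.

Uncertainty in the seasonal particle concentration is propagated with a
bootstrap: station concentrations are resampled with replacement (1000
repetitions by default), each resample mean is pushed through the rate
formula, and the mean ± SD of the resulting rates is reported at every
depth. Per-station values for the original survey were never published —
only summaries (June: n = 10, 13.5 ± 7.1 particles L⁻¹; October: n = 7,
2 ± 1.7 particles L⁻¹) — so the package ships synthetic station sets
matching those summaries, and a generator to build your own.

A brute-force Monte-Carlo oracle (ballistic agents in a periodic box,
continuous-time sphere-crossing detection) validates the closed forms
independently; see `zooencounter oracle-check`.

## Worked example

```python
from zooencounter import run_full_study

study = run_full_study(seed=42, n_reps=1000)
print(study.summary())
```

prints

```
Encounter-rate study: 12 profiles (seed 42, 1000 bootstrap repetitions)
 season       taxon  gs_surface_rate_per_h  ro_surface_rate_per_h  turbulence_multiplier
   june chaetognath                 2500.0                 3490.0                    1.4
   june     copepod                    1.5                    1.8                    1.2
   june   luciferid                  998.0                 2670.0                    2.7
october chaetognath                  366.0                  603.0                    1.6
october     copepod                    0.2                    0.3                    1.3
october   luciferid                  146.0                  507.0                    3.5
```

Each row is one season/taxon: the calm-water (GS) and turbulent (RO) surface
encounter rates in particles per individual per hour, and their ratio (the
turbulence multiplier, independent of particle concentration). A chaetognath
cruising June surface water meets on the order of 2500 particles per hour
because of its large (20 mm) perception radius; a copepod, perceiving
particles only within 0.4 mm, meets between one and two. June rates exceed
October rates for every taxon — concentration (13.5 vs 2 particles L⁻¹)
dominates the stronger October wind. The multiplier grows as swimming speed
shrinks relative to the turbulent velocity, so the slow luciferid benefits
most from turbulence (×2.7–3.5) and the fast copepod least (×1.2–1.3).

Single profiles come from the model class directly:

```python
from zooencounter import BootstrapConfig, EncounterProfileModel, default_scenarios

model = EncounterProfileModel(default_scenarios()["june"], "chaetognath", "ro")
result = model.fit(BootstrapConfig(n_reps=1000, seed=42))
print(result.summary())
```

```
Encounter rate profile: chaetognath, june, RO model
  bootstrap: 1000 repetitions, seed 42
  surface rate: 3494.43 ± 526.295 particles ind^-1 h^-1
  bottom rate (1.5 m): 2496.03 ± 375.926 particles ind^-1 h^-1
```

The same machinery is exposed as a CLI: `zooencounter run-season`,
`run-full-study`, `turbulence-profile`, `simulate-stations`, `oracle-check`.

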
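# Methods

## Model overview

`turtledrift` is a Lagrangian individual-based model of oceanic-stage sea
turtles. Each agent carries a position, a release (birth) date and a
cold-exposure counter. Once a day, for every living agent, the model:

1. looks up water temperature `Tw` and net primary production `NPP` at
   the agent position (bilinear in space; the time axis is daily, and
   simulations longer than the stored forcing loop it periodically);
2. evaluates the age-specific habitat suitability `h = h_F·h_T` and its
   gradient on the forcing grid, and interpolates both to the agent
   position;
3. draws a heading `θ ~ vonMises(μ = dir ∇h, κ = α‖∇h‖)` and swims with
   velocity `V_m(a)·(1−h)·d(θ)` (active mode; passive mode sets the
   swimming term to zero and skips the habitat machinery entirely);
4. advects the agent with `V_g = V_c + V_s` for 86 400 s;
5. updates cold-exposure bookkeeping: death after `Tw < T1(a)` on 10
   consecutive days.

Assumptions worth making explicit: agents sense only `h` and `∇h` (no
current detection or compensation, no navigation memory); headings are
redrawn independently every day (no persistence); surface currents stand
in for the depth-averaged flow (diving is not represented); there is no
starvation mortality, growth plasticity or density dependence. Ages are
kept in days and converted with 365.25 d/yr wherever the allometric
relations need years.

## Parameters

Leatherback defaults of `SpeciesParams` (all overridable per run):

| parameter | value | units | role |
|---|---|---|---|
| `L_inf`, `growth_rate`, `age_shift` | 1.43, 0.226, 0.17 | m, 1/yr, yr | von Bertalanffy growth |
| `mass_coeff`, `mass_exp` | 112.31, 2.86 | kg·m⁻ᶜ, — | mass–length law |
| `rmr_mass_exp` | 0.831 | — | RMR mass scaling; with `mass_exp` gives the speed exponent (bc−2)/3 = 0.126 |
| `v0` | 1.2 | m/s | speed scale; recovered from tracked mean speeds ≈0.6 m/s at average habitat h = 0.5 |
| `alpha` | 3×10⁶ | m | κ = α‖∇h‖; recovered from κ = 4 at the basin-median gradient ≈1.3×10⁻⁶ m⁻¹ |
| `body_temp_min`, `d0`, `activity_ratio_max` | 24, 0.21, 5 | °C, °C·kg⁻⁰·⁵, — | cold pivotal temperatures T1, T2 |
| `f0`, `food_age_rate` | 0.094, 0.299 | —, 1/yr | normalized food consumption F0(a) |
| `P0` | 55 | mmol C m⁻² day⁻¹ | NPP level saturating the adult feeding habitat |
| `T3`, `T4` | unset | °C | warm preferendum/critical bounds (not reached by leatherbacks) |

The food-consumption curve is
`F0(a) = f0·x·(1−x)^1.86 / (1 − (1−x)^0.094)` with
`x = e^(−0.299(a+0.17))`; its shape constants 1.86 and 0.094 are held as
opaque calibrated values, and the large-age limit is `f0/0.094`, i.e. 1
at the default `f0`. It is evaluated with `log1p`/`expm1` so the limit is
numerically exact.

`EnergeticsParams` (RMR, ρ, C_D, S, η) exists only to verify the
work-per-meter minimization structurally — the closed form
`(ηRMR/ρC_D S)^{1/3}` is tested against a numerical argmin — because all
of these constants cancel into `v0` in the operational speed law.

Run-level knobs: cold threshold 10 days in consecutive mode (a warm day
resets the spell; a cumulative mode is available because "10 days or
more" could also be read as lifetime exposure), coast handling free-slip
(default; a "reflect" mode mirrors the blocked displacement component),
habitat age-binning 0.1 yr (fields are computed once per day per age bin;
speed and thresholds change well under 1 % across a bin), κ capped at
10⁴ to keep the sampler away from degenerate concentrations.

## Numerical choices

* **Interpolation.** Bilinear between the four surrounding ocean cell
  centers with land cells dropped and the weights renormalized, so
  coastal values are not dragged toward zero-filled land. A fully land
  stencil is reported to the caller as "on land".
* **Gradients.** `∇h` is computed at cell centers by centered finite
  differences with metric spacings `Δx = R·cos(lat)·Δλ`, `Δy = R·Δφ`
  (R = 6 371 000 m, gradients in m⁻¹). Next to land or a domain edge the
  difference degrades to one-sided rather than treating land as `h = 0`,
  which would fabricate strong artificial coastal gradients; with no
  ocean neighbor on either side the component is 0. Cell-center gradient
  components are interpolated bilinearly to agent positions, an
  extension over evaluating them on the nearest cell.
* **Integrator.** One explicit daily step; the latitude advances
  metrically and the longitude conversion uses the midpoint latitude of
  the step (one Heun pass). With daily-averaged forcing and 86 400-s
  steps, higher in-step accuracy has nothing to act on, and the simple
  scheme can be pinned trajectory-for-trajectory against an independent
  re-implementation (which the tests do).
* **Heading sampler.** numpy's `Generator.vonmises` (Best–Fisher
  rejection) driven by a stream spawned from the run seed; κ = 0 yields
  exactly uniform headings. The sampler is validated against the closed
  form: KS uniformity at κ = 0, χ² goodness of fit and the >90°-deviation
  tail (≈0.0076 by numerical integration) at κ = 4, and circular-mean
  convergence at large κ.
* **Degenerate inputs.** Negative NPP (satellite artifacts) clamps to 0
  with a logged warning; a zero food threshold saturates `h_F` at 1;
  agents stepping across the domain boundary are frozen and flagged
  "exited" and drop out of diagnostic denominators; ties at the
  crossing-time group boundary (N ± 6 months) round up.

## The synthetic basin

The generator builds, on a 1° grid over 120–280°E × 0–50°N with a 365-day
period, the minimal oceanographic structure that makes the model's
qualitative behaviors emerge:

* **Circulation** from an analytic streamfunction: an eastward jet
  (0.4 m/s peak at 35°N), an eastward low-latitude countercurrent
  (0.3 m/s at 6°N), a broad westward return flow between them whose
  amplitude solves a 3×3 linear system so the configured peaks are exact
  and the basin-integrated transport closes, plus the meridional limbs
  that recirculate along the boundaries. A travelling meander wave
  (0.12 m/s, 73-day period) centered on the tropical flank breaks the
  closed streamlines; without it, advection is integrable and released
  drifters never cross between the tropical cell and the subtropical
  gyre. Velocities come from *spherical* centered differences of the
  streamfunction sampled at cell centers, which makes the discrete
  spherical divergence cancel identically on interior cells.
* **SST** warm (28 °C) and aseasonal in the tropics, dropping through a
  tanh front at 35°N to 8 °C, with a seasonal cycle growing across the
  front to ±9 °C at the pole (±4.5 °C at 35°N, comparable to observed
  transition-zone seasonal ranges). The profile is monotone poleward on
  every day of the year by construction.
* **NPP** with an oligotrophic gyre core (8 mmol C m⁻² day⁻¹ floor with
  a weak poleward tilt), a rich transition-zone band at 40°N decaying
  west to east (80 → 20), a seasonal pulse peaking in summer, and an
  eastern-boundary upwelling strip north of 25°N. The westernmost and
  easternmost columns are land, standing in for the continental coasts.

On this basin, a 500-agent cohort released in a 0.25° box at
(137°E, 13.5°N) between June and November (truncated-normal dates peaking
September 15, σ = 30 d — the spread is not a published value and is
config-exposed) reproduces the model's qualitative fingerprints within 6
simulated years: drifters carried north young die in the cold winters
while active agents retreat south and survive (passive cumulative
mortality ≈ 0.33 vs 0 active at these conditions); settled active cohorts
oscillate annually in mean latitude with an amplitude of ≈2.6° (annual
harmonic plus linear trend fitted over simulation years 4–6, after the
arrival ramp) while the passive cohort shows none; and the mean zonal
swimming velocity of age-3+ agents inside the jet band is westward,
against the prevailing drift, because food is richer to the west.

What the basin does **not** emulate: mesoscale eddies and realistic
boundary-current widths, interannual variability, coastline geometry,
cloud gaps in satellite NPP, or the real basin's absolute magnitudes.
Published real-ocean numbers (absolute mortality percentages, crossing-
time histograms, mean current speeds along crossing corridors) depend on
the original multi-year ocean reanalysis and satellite NPP archives and
are therefore *not* targets here; the tests assert the corresponding
sign, ordering and existence properties instead. Passing them shows the
mechanisms are implemented and interact correctly, not that the synthetic
ocean is a substitute for forcing the model with real data.

## Problem sizes

The test suite runs the scaled-down cohort (500 agents, 6 years, both
modes, shared by all emergent checks through one session fixture; about
15 s for the active run on one core), 10⁵-draw sampler statistics, and
desk-scale oracle checks. The full study configuration (5000 agents, 18
years) is the config default and runs in minutes to tens of minutes
depending on forcing resolution.

## Known limitations

* Trajectories are recorded densely (one record per agent-day); very
  large runs should prefer the netCDF writer over CSV.
* The free-slip coast rule resolves a blocked step axis-by-axis; on
  strongly diagonal coastlines agents can stall in concave corners.
* Habitat fields are evaluated per (day, age-bin) with no cross-day
  caching; forcing grids much finer than ~0.1° will make the active mode
  field evaluation the dominant cost.
* `h` at an agent's position is interpolated from cell-center values of
  the *already composed* index; composing after interpolation would
  differ slightly in strongly curved habitat fields.
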
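# Methods

## Growth

Each of the ten dominant species classes carries a fitted DBH–age curve of
one of two families, both strictly increasing and bounded by an asymptote
`A` (cm):

* saturating (Chapman–Richards): `DBH(t) = A·(1 − e^(−k·t))^p`, zero at age 0;
* Gompertz: `DBH(t) = A·e^(−b·e^(−k·t))`, equal to `A·e^(−b)` at age 0
  (a small nonzero sapling diameter — for Pinus about 6 cm).

The curves, their residual errors (cm) and each class's canopy fraction are
packaged in `data/species_growth.csv`; the fractions of the classes that
have one sum to exactly 100%. The "mix" class — canopy that could not be
assigned a dominant species, 26.5% of the total — is the unweighted
arithmetic mean of the ten curve *outputs*; a canopy-fraction-weighted
variant is available but is not the default, since the class is defined as
the plain average of the member equations. Growth is deterministic; the
printed residual errors are used only, and only optionally, as one-time
mean-zero DBH noise at inventory construction (per-year noise would break
monotonicity).

Ages are real-valued in the functions and advance in whole-year steps in
the simulation loop.

### Inversion

Both families invert in closed form (saturating:
`t = −ln(1 − (D/A)^(1/p))/k`; Gompertz: `t = −ln(−ln(D/A)/b)/k`), and the
round trip is exact to < 1e−6 years over [0, 200] years for all ten
classes. The mix curve has no closed-form inverse and is inverted by
Brent's method on [0, 2000] years with 1e−9 tolerance.

Diameters at or above a class asymptote are unattainable on its curve —
a real concern, since the Tilia asymptote (56.5 cm) is below plausible
urban diameters. The default policy caps the age at the point where the
curve reaches `(1 − ε)·A` (ε = 1e−3) and emits a warning, keeping large
real trees usable while making the distortion visible; a strict mode raises
instead. Diameters below a Gompertz age-0 value clamp to age 0 with a
warning.

## Biomass and carbon

Above-ground dry biomass is a power law `B = a·D^c` (kg, D in cm) resolved
per species class through an `allometry_key`. Species-calibrated published
equations differ by source and are not bundled; the packaged defaults are
two synthetic generic temperate parameterisations (broadleaf a = 0.12,
conifer a = 0.10, both c = 2.4, nominal validity 5–80 cm) chosen once as
order-of-magnitude-realistic for temperate urban trees. Consequently
absolute pool magnitudes (ktC, tC/ha) scale with the supplied table, while
everything demographic — counts, ages, half-lives, trajectory shapes and
orderings — is allometry-independent (tested). Users reproducing a
specific study should supply its equations as a replacement CSV. Out-of-
range diameters are evaluated rather than clamped, so totals stay smooth;
they are logged at DEBUG level. No urban correction factor is applied.
Mix-class biomass is the average of the ten per-model biomasses at the same
DBH (average-of-biomasses, not biomass-of-average).

Carbon is `0.5 ×` dry biomass; the fraction lives in the run configuration
and is overridable.

## Synthetic inventory

The generator emulates the statistical structure of a remotely sensed
city-wide inventory (~1.4 M trees, mean height 15 m, mean DBH 36 cm):

* species classes drawn from the canopy fractions (mix 26.5%);
* land-use classes street/mixed/park with a shipped default split of
  0.20/0.45/0.35 — a configuration default, since no observed split is
  available;
* ages from per-land-use truncated normals, street 49 ± 15 y, mixed
  52 ± 17 y, park 56 ± 15 y, truncated at 1 year. Truncation shifts the
  means by < 0.05 y at these parameters. The family is a modelling choice:
  only means and SDs of the real age structure are known, and the truncated
  normal controls both moments;
* DBH derived from age through the class growth curve (mix curve for mix
  trees), so mean DBH is *implied* (~35 cm at mean age ~53) rather than
  forced to the 36 cm reference; an optional calibration check warns when
  the generated mean leaves a ±15% band around 36 cm. Forcing both age and
  DBH moments would break the growth-curve relationship the simulation
  depends on;
* heights from a monotone height–DBH rule for completeness only — the
  carbon path never reads them; coordinates optional and uniform.

The generator produces no spatial clustering, no understory/small trees,
no species–land-use correlation and no measurement error model beyond the
optional residual-error noise, so passing tests demonstrate correct
pipeline mechanics and moment recovery, not realism of any particular
city's inventory.

## Mortality and half-life

Annual static rates per land-use class (street 0.035, mixed 0.02, park
0.01 by default), applied by stratified random selection. Stratification is
by land use only; an optional species stratification is deliberately not a
default. Two modes:

* **stochastic** — Bernoulli thinning per alive tree; death-year records
  carry the tree's full current-year carbon into the dead pool.
* **expected_value** — exact expectation accounting. The rate depends only
  on the class, so every member's survival probability after *t* years is
  `w_c(t) = (1 − m_c)^t`; expected alive carbon is `w_c(t)·Σᵢ cᵢ(t)` and
  the dead-pool increment in year *t* is `(w_c(t−1) − w_c(t))·Σᵢ cᵢ(t)`.
  Populations are continuous (fractional) in this mode; the standalone
  mortality operation additionally marks `round(m_c·alive_c)` integer
  records per year so CSV outputs keep meaningful death years.

The population half-life of a cohort under static rate *m* is the smallest
integer *t* with `(1 − m)^t ≤ 0.5`, computed as `ceil(ln 0.5 / ln(1 − m))`
with explicit floating-point guards; the three default rates give 20, 35
and 69 years. No maximum-age kill switch exists — trees keep growing on
their curves indefinitely — but reports flag populations whose average age
exceeds 80 years (strictly) as highly uncertain.

Planted cohorts start at age 0 on the mix curve (small nonzero DBH from the
Gompertz members); no sapling size or young-tree mortality premium is
modelled.

## LCA engine

Within each simulated year the order is grow → prune → die, chosen so that
dying trees carry their current-year biomass into the accumulated dead
pool. Pruning (default **off**) removes a fixed fraction (10%) of each
alive tree's above-ground carbon every pruning interval (10 y) and credits
it to the dead/residual pool; because DBH is refreshed from the growth
curve each year, pruning affects that year's pools, not the growth
trajectory. The dead pool never decays (a decay hook is a no-op extension
point); emissions from maintenance, planting, irrigation, removal and
decomposition are out of scope. Reports are emitted at the start year
(default 2008) and every interval (default 10 y) through the horizon
(default 60 y, with a final partial interval reported if the horizon is not
a multiple), per land-use class and in total. Densities divide every pool —
alive and dead alike — by the fixed analysed land-cover area (default
70,000 ha).

## Numerical choices

* Mix-curve inversion: Brent on [0, 2000] years, xtol 1e−9; unattainable
  diameters use the same cap policy with the mean of the ten asymptotes as
  the effective asymptote.
* Half-life: `ceil` of the log ratio with a two-sided integer correction
  loop to guard boundary floating-point error.
* Expected-value rounding: integer record deaths use `round`, ties to even
  (Python banker's rounding); pool arithmetic never rounds.
* Empty populations report `None` averages and an undefined (absent)
  uncertainty flag rather than zero/false.
* One user seed per run; per-module substreams are derived as fixed small
  offsets so module execution order cannot perturb results.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at 1,000 to
100,000 synthetic trees and 200 stochastic cohort replicates — sizes chosen
so the full suite completes in a few minutes on one core while keeping
Monte-Carlo standard errors well inside the asserted 3-SE bands. The
engine is vectorised per species class and year; a 60-year run over 10⁵
trees takes a few seconds, and larger inventories scale linearly.

## Known limitations

* Absolute carbon magnitudes depend entirely on the allometry table; the
  defaults are generic and not species-calibrated.
* Static, age-independent mortality; no replanting schedules beyond a
  single cohort; no climate or site modification of growth.
* The synthetic inventory reproduces moments, not spatial structure.
* Dead biomass is accumulated forever; real decomposition or reuse would
  change the net balance qualitatively.
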
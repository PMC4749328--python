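# Methods

## Scope and state

`swanstage` simulates autumn staging of Bewick's swans on a tuber landscape
in a water-level-managed lake at an hourly time step over a two-month
window. State consists of (i) per-patch tuber biomass density *D* (g dry
mass m⁻²), the only depletable resource; (ii) per-super-individual location
and energy store (J per swan, flocks of 20 swans share one state); (iii) the
hourly lake level (m NAP). Water levels feed back on foraging through
accessibility and nothing else; tubers do not grow or die within the season;
there is no starvation mortality, no dominance structure, no day/night split
of the time budget, and no interaction with diving ducks.

## Water-level sub-model

The sea (tide) side of the sluice forces the lake: each hour, if the sea is
at or above the lake the level rises by the build-up rate (0.01 m h⁻¹,
hinterland inflow; a tie counts as build-up since drawdown needs a positive
head); if the sea is lower and the lake is above target it falls by the
drawdown rate (0.15 m h⁻¹) but lands exactly on the target rather than
undershooting (partial-hour drawdown); at or below target with the sea lower
the level holds. Build-up also applies below target — water flows in
regardless of the management goal. Both rates are recoverable by a
documented grid search (drawdown 0.05–0.30 by 0.01, build-up 0.005–0.030 by
0.0025 m h⁻¹) minimizing hourly squared error, with R² = 1 − SSE/SST; a
constant observed series is rejected (R² undefined, tested via the range of
the series, not a floating-point SST).

One property worth stating precisely: raising the target *does not*
pointwise raise every hourly level. When the higher-target lake draws down
onto its target in an hour when the lower-target lake happens to build up,
the trajectories cross transiently, bounded by one drawdown plus one
build-up step. The minimum level and the level floor are ordered; the full
trajectories are ordered only up to that slack.

Patch depths are standardized at the reference level (−0.93 m NAP, the
current management target): actual depth = standardized depth + (level −
reference). Scenario sweeps change the sluice target while the reference —
a property of how depths were measured — stays fixed.

## Foraging and departure

Intake is a type II functional response on the accessible density
*A(d)·D*, scaled by the foraging time budget *f* = 0.66, the
area-restricted-search benefit *b* = 1.38, the time-underwater fraction and
attack rate of the sediment, and a fitted quartic interference polynomial
*i(N)* in swans m⁻². Numerical guards, all documented as deliberate: *A(d)*
is clamped to ≤ 1 (the quadratic exceeds 1 for clay just past the 0.51 m
head-dip bound); *i(N)* is clamped to [0, 1] (the quartic diverges outside
its fitted density range, going negative above ~0.06 swans m⁻²); depths
shallower than 0.10 m give *A* = 0 rather than removing the patch, because
levels fluctuate hourly and suitability must be dynamic. Interference
density counts individual swans (20 per flock), not flocks.

Net gain is `q·e·I` minus a time-budget-weighted cost: foraging cost per
patch type (larger on clay and in deep water) and, for the non-foraging
fraction, the mean of resting and preening. A swan leaves for the
surrounding beet fields when the *best obtainable* gain over all patches
drops below `p·(MEI_b − DEE_b)/86400` ≈ 36.8 J s⁻¹ — the field alternative
discounted by the perceived predation risk there — and departs satisfied
when its store reaches the target (≈49 MJ). Under the defaults this gives a
giving-up tuber density of ≈7.2 g m⁻² on fully accessible sandy-shallow
ground, rising as accessibility falls.

## The hourly step and its open choices

Within a step: arrivals are admitted, every present flock decides in a
freshly randomized order (occupancy updates between movers, so flocks do not
pile onto one patch on identical information), then foraging, depletion and
store dynamics are applied patch by patch. Choices the source material left
open, fixed here:

- **Census hour 12:00** (configurable): daily counts were daytime telescope
  counts; arrivals enter at 06:00 so an arrival day counts.
- **Departure checks**: the store-target check runs at the start of a
  flock's decision turn and again after accrual; emigration is checked
  during the decision turn. A flock whose store hits zero is floored at zero
  and leaves as a field emigrant.
- **Flight cost in comparisons**: a candidate patch in another inlet is
  scored as gain minus the fixed flight cost amortized over one hour;
  actually flying costs the 53 kJ and the hour (no foraging that step).
  Within-inlet moves are free; between-inlet distance is the published mean
  (3317 m), above the 3316 m threshold. The fixed cost uses the in-text
  formula 3316/12.8 × 204 = 52 848.75 J; the alternative printed rounding
  (52 699 J) is selectable by configuration.
- **Depletion removes total density**, not only the accessible portion:
  accessibility already discounts availability inside the functional
  response, and tuber density changes by depletion alone. Removal per patch
  is capped at the standing crop, with per-swan intake scaled down
  accordingly, so tuber mass is conserved exactly: over any run, Σ area ×
  (D_initial − D_final) equals total grams ingested to ~10⁻¹⁵ relative.
- **Arrivals placed at their argmax patch** with no arrival flight cost
  (migration costs are outside the model boundary); arrival dates are
  normal draws rounded to days, clipped to the window start; draws past the
  window end never arrive. A flock still present when the window closes is
  recorded with reason `season_end` (the published reason set has no such
  category because two months comfortably exceed observed staging times;
  it appears only in degenerate configurations).

Ties prefer staying, then the lowest patch index. All randomness flows from
one `numpy` generator per run; replicate and scenario streams derive from a
base seed by a splitmix-style hash kept below 2³¹. Identical seeds give
bit-identical results.

## Synthetic study inputs

The generators reproduce the statistical structure of the study system, not
its geography:

- **Tide**: semidiurnal sine (12.42 h) with spring–neap amplitude
  modulation (14.77 d) plus Gaussian noise. Constants (mean 0.0 m NAP,
  amplitude 1.30 m, modulation 0.65 m, noise SD 0.05 m) were calibrated once
  so that, under sluice management at −0.93 m NAP, drawdown is blocked long
  enough around neap that the lake occasionally rides ≥ 0.25 m above target,
  and at a −0.73 target the shallow patches sit past the 0.51 m head-dip
  depth every hour. Scenario analyses use one fixed forcing realization per
  year (`study_forcing`), mirroring a study that ran all scenarios against
  one observed gauge record per season; it is not redrawn per run.
- **Patches**: the four sediment × depth-class types at the measured
  year-specific mean densities, with optional dispersion Normal(mean,
  SE·√N) truncated at zero; class-mean standardized depths 0.33/0.62 m.
  True per-inlet areas are unpublished, so the default splits 10⁷ m²
  (about half the lake) uniformly over the four types — the one structural
  input that cannot match the real site.
- **Counts**: modelled daily counts with Poisson (or proportional) noise
  and a 6% mask of interior days linearly interpolated, like the field
  protocol's observation gaps.

Passing tests on these inputs show the machinery and the emergent threshold
response; they do not validate the model against the real lake, whose
forcing, patch areas and count series are not published as data.

## Calibration, sweeps, elasticities

Calibration scores candidate incoming totals (3000–6000, step 500) by SSE
between replicate-mean modelled daily counts and the observed series
(cumulative-count SSE available as an option; daily is the default, with
bird-days and peak reported alongside). Identifiability has a real limit:
between-realization SD of a season's counts at a fixed total is about half
a 500-swan step under the synthetic forcing, because arrival draws interact
with neap high-water episodes. Self-recovery with the pipeline's own seed
stream is exact (18/18 across totals and seeds, with Poisson count noise);
against fully independent realizations the estimate is only guaranteed
within one grid step, and interpolated observation gaps on steep arrival
days add error that carries no information about the total. Calibration
runs N = 4 replicates, the study's replicate count.

Target-level sweeps regenerate lake levels per target (−1.13 to −0.73 m
NAP by 0.10) and rerun N = 4 replicates with seeds shared across targets
(common random numbers; results are independent of evaluation order).
Under the 2005 configuration, a +0.20 m rise removes ~97% of bird-days
while −0.20, −0.10 and +0.10 m stay within replicate noise — the headline
nonlinearity. Two second-order emergent effects are worth knowing:
(1) lowering the target makes deep patches fully accessible, so swans
refuel faster and leave sooner — a systematic ~5–15% bird-day *reduction*
that can exceed the small replicate SDs for some seeds; (2) in the rich
2006 landscape the shallow patches remain profitable even 0.20 m up, and
the collapse shrinks to ~16% — the threshold's location depends on food
density, not only on depth.

Elasticities are one-at-a-time ±10% central differences of replicate-mean
bird-days with common random numbers. They are regime-dependent: on a lean
landscape near the giving-up density, energy density *e* and efficiency
*q* have strong positive elasticity (they lower the giving-up point) and
handling time *h* a clear negative one; on the calibrated 2005
configuration the refuelling-speed effect dominates and *e*, *q* turn
*negative* (faster satiation, shorter stays) while *h* is near zero. The
strongest levers on the calibrated configuration are the beet-field terms
(*p*, MEI_b) and the store targets, consistent with departure decisions,
not intake, limiting usage.

Observed-vs-modelled comparison uses a paired t-test and OLS of observed on
modelled with 95% confidence limits for intercept and slope.

## Problem sizes and runtime

Default problem sizes — 61 days × 24 h, 150–300 flocks, 4-patch landscape,
N = 4 replicates — run a full season in ~0.2 s, the five-level sweep in
~3 s and a full calibration in ~15 s on one core, so the entire analysis
suite and test suite complete in about a minute.

## Known limitations

Patch areas and per-inlet structure are invented defaults; the interference
polynomial is used outside its fitted range only via clamping; foraging
costs depend on depth class, not actual depth, so a deep patch under a low
lake keeps its deep-class cost; perfect knowledge overstates information on
buried prey; and the two-month window truncates late arrivals rather than
following them. Long-term vegetation response to a regime change is out of
scope: the model answers the short-term carrying-capacity question only.
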
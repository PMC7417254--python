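# Methods

## The detection problem

A pregnant lioness becomes strongly localised around parturition: she
selects a den, travels far less, and stays within a few hundred metres
of one point for weeks while nursing. `liondens` turns that signature
into an inference pipeline over GPS collar data sampled on a nominal
4-hour schedule:

1. **Movement indicators** per female and calendar month:
   - *daily net displacement* — step lengths between consecutive fixes,
     aggregated per civil day (boundary at UTC+2, configurable);
   - *residency clusters* — maximal runs of consecutive fixes within a
     200 m radius of the running cluster centroid, the proxy for a den
     or carcass site;
   - *monthly range isopleths* — 50% core and 90% total areas from the
     k-nearest-neighbour local convex hull (k-LoCoh) estimator.
2. **Birth-month scoring**: each month is scored against the female's
   own baseline, conception is backdated three calendar months
   (lion gestation at monthly resolution), and events are tallied by
   wet/dry season and related to prey birth pulses through binomial
   GLMs compared with AICc and Akaike weights.

## Movement indicators

**Distances** are great-circle (haversine) on a sphere of radius
6371.0088 km. At the 200 m cluster scale the spherical error is far
below a metre, and no projected CRS is needed for distances.

**Daily net displacement** supports two aggregations of a day's step
lengths: their arithmetic mean (`how="mean"`) and their sum
(`how="sum"`, the distance travelled that day). The published regional
levels (7.2 km/day south, 9.1 km/day north) are daily-travel figures:
on a 4-hour schedule a 7.2 km *mean step* would be geometrically
incompatible with monthly ranges of ~20 km² (the step would exceed the
range diameter), while 7.2 km of *daily travel* inside such a range is
textbook lion movement. The generator therefore calibrates, and the
calibration tests measure, the `how="sum"` quantity; the mean-step form
remains available and is the literal per-step average.

**Residency clusters** use a greedy forward scan: a fix joins the open
cluster iff it lies within `radius_m` (default 200) of the running
centroid of the fixes accepted so far; otherwise the cluster closes
(kept iff it has ≥ `min_fixes` = 3 fixes, i.e. ≥ 8 h of residency) and
a new one opens. The running-centroid anchor is robust to slow drift; a
first-fix anchor is available as an option. Missed fixes never break a
cluster — with 10–15% failure rates a gap rule would shred every
residency — only a received fix outside the radius does. An exhaustive
scan oracle verifies the greedy implementation on random trajectories.

**k-LoCoh isopleths**: for each point, the convex hull of the point and
its k nearest neighbours (ties broken by point index); hulls sorted by
ascending area (ties by parent index); the union accumulated until it
covers the target fraction of points, counting a point as covered when
inside *or on the boundary* of the union. Degenerate hulls (collinear
neighbour sets) have zero area but still count toward coverage, which
keeps the accumulation well defined. `k = ⌈√n⌉` by default (the usual
square-root heuristic), exposed in configuration. The minimum convex
polygon is implemented independently as an oracle: LoCoh at
`k = n − 1`, fraction 1.0 must equal the MCP area to 1e-9.

Geographic points are projected to a local plane with a spherical
azimuthal equidistant projection about the point centroid, which
preserves distances from the centroid exactly and areas to first order
at home-range scale; the inverse projection restores WGS84 coordinates
for GeoJSON output.

## Birth-month scoring and calling

Monthly indicators are z-scored against the female's own months using
the median/MAD (consistent with the normal, capped at ±8; the MAD
guards against the den month polluting its own baseline). The score is

    w_core · z(−log core50) + w_res · z(residency) + w_disp · z(−travel)

with default weights (0.6, 0.2, 0.2). A single-indicator score weighted
by the published candidate-model table would be degenerate — the
step-length models carry ~4e-4 of the weight and duration of stay was
never modelled (the published analysis dropped it as subjective) — and
core size alone cannot separate a den from a month spent at two
long-lasting carcasses, which also yields a tiny 50% isopleth. The
residency indicator is what distinguishes those cases, so it keeps real
weight.

Candidate months are tiered before scoring: months overlapping an
unbroken residency of at least `min_den_residency_days` (default 12)
rank ahead of all others. This mirrors the published pipeline order —
fix clusters identify the *potential* birth month, range contraction
and displacement verify it — and encodes the biology that denning lasts
weeks (mean ≈ 19.7 days) while carcass attendance lasts days
(mean ≈ 4.9). A birth is *called* when the top-ranked month shows such
a residency and its score exceeds the call threshold (default 2
z-units; the original study used field verification instead, so the
threshold is exposed in configuration).

Conception backdating is exact calendar arithmetic (Period − 3 months,
year rollover included); backdate-then-advance is the identity for
every month/gestation combination, tested exhaustively.

## Seasonality and ecological association

Called (or true) events become female × month binary outcomes over the
environment calendar: 1 in the event month, 0 elsewhere. The response
is binary by construction, so the association models are binomial GLMs
with a logit link (the source description "Poisson regression on a
binomial distribution" is internally contradictory; the stated 0/1
coding decides it). Predictors are the wet-season indicator and the
prey birth-pulse indicator; covariate columns that add no rank (e.g.
pulse coinciding with season over a short span) are dropped. Complete
separation is detected from runaway coefficients and handled by an
L2-penalised refit, flagged on the result. All fitted rows form one
candidate set: AICc, Δi and Akaike weights are computed jointly, with
log-sum-exp stabilisation so weights sum to 1 to 1e-12.

For the published candidate tables, the effective sample size for AICc
is n = 20 (the number of collared females); this value uniquely
reproduces both printed AIC→AICc gaps (+0.22 at k = 1, +0.71 at k = 2)
and is configurable.

## The synthetic telemetry generator

No public collar data exist for the study system, so `synth` generates
studies with the documented statistical structure. What it emulates:

- two regions — south (high prey biomass, ~750 mm rain) and north (low
  biomass, ~450 mm) — with the wet season October–March carrying ~80%
  of annual rainfall and prey pulses in October and January–March;
- a 4-hour fix schedule with Bernoulli fix failure (15% south cellular
  collars, 10% north satellite collars);
- ranging as a home-attracted correlated random walk: gamma step
  lengths (shape 3), von Mises turning noise (κ = 2), and a
  home-centre pull calibrated so monthly point clouds give ~3.4 km²
  LoCoh cores and ~15–20 km² total ranges;
- multi-day feeding stops (mean 4.9 days, ~1/month) at the female's
  current position, confined to a ~90 m neighbourhood — the background
  residency signal;
- for pregnant females, a denning window (mean 19.7 days, SD 2.5)
  confined to a ~178 m disc around the den, with a tight post-partum
  ramp-in and rare (0.2%/fix) short excursions; conception months are
  drawn so ~73% (south) / ~71% (north) fall in the wet season, births
  follow 3 months later.

Denning onset is placed inside the calendar birth month so that the
expected number of denning days in that month reproduces the configured
birth-month travel contraction (3.08 km/day south, 5.81 north); the
window spills into the following month, which is why the full ~19.7-day
residency coexists with only a partial within-month travel collapse,
exactly as in the published contrasts. Ranging step means are set
analytically from the daily-travel targets, correcting for stop-day
dilution and for the path shortening caused by fix dropouts (a linear
shrink of 0.6 × failure probability, fitted once against the generator
itself).

Determinism: one master seed; per-female and per-stream generators are
derived via CRC32 hashing of stable identifiers, so output is bitwise
reproducible and independent of iteration order. Same seed ⇒ identical
CSV bundles.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: GPS positional error (real fixes carry
tens of metres of noise), habitat- or water-driven space use, prey
dynamics feeding back on movement, social structure (pride-mates,
crèches, male takeovers; an optional birth-synchrony knob exists but no
default behaviour is claimed faithful), den relocation, and
collar-failure gaps longer than independent fix dropouts.

### A geometric note on the pregnant core range

The published pregnant-month core (~0.2 km², SE 0.1) cannot be realised
jointly with an unbroken multi-week 200 m residency: confinement within
200 m of a centroid caps the den neighbourhood at π·0.2² ≈ 0.126 km²,
and the 50% LoCoh isopleth of a uniformly used den disc covers only
part of that (~0.04–0.1 km² at k = ⌈√n⌉). The calibration tests
therefore assert the attainable content of the contrast — the
nonpregnant core level (3.4 km² ± 15%), the geometric cap, and a
contraction ratio below 0.1 (published ratio 0.2/3.4 ≈ 0.06) — rather
than the absolute printed mean, whose value presumably reflects
positional noise and less strict confinement in the real collars.

## Numerical choices and degenerate inputs

- Weights via log-sum-exp; Δi ≥ 0 with one exact zero (up to ties).
- ANOVA with zero variance everywhere returns an undefined-F flag
  (NaN + warning); Kruskal–Wallis on all-identical data returns H = 0.
- All-collinear point sets yield zero-area isopleths with a warning.
- Months with fewer than max(10, k + 1) fixes carry no range estimate
  and are excluded from scoring baselines (NaN-safe z-scores).
- Cluster ties and hull-area ties break deterministically by index;
  candidate-month score ties break toward the earlier month.
- Files carry 6-dp coordinates (≈ 0.1 m) and ISO-8601 UTC timestamps;
  internals keep full precision.

## Problem sizes in the test suite

The default synthetic study is 20 females (12 pregnant, split 6/6 by
region) over 36 months — the published cohort shape. Recovery is
assessed over 20 seeds of that study (480 female-studies); seasonality
calibration uses 500 pregnant females drawn as truth records (the
trajectory layer adds nothing to that quantity); estimator property
checks use 200 random point sets and 100 random trajectories. These
sizes keep the full suite in the minutes range on one CPU while leaving
Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

- Calendar-month resolution: births near month boundaries can top-rank
  the adjacent month; recovery is therefore judged at ±1 month.
- The residency gate assumes carcass attendance stays under ~12 days;
  ecosystems where lions hold kills longer would need a higher gate or
  revisitation-based den/kill discrimination, which is out of scope.
- The score weights are a design default, not an estimate; with real
  verified births they should be re-fit.
- Kruskal–Wallis and ANOVA are provided for fecundity-style group
  comparisons, but published cross-park fecundity statistics are
  literature values whose exact test layout is not reconstructable, so
  no numerical claims are made about them.
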
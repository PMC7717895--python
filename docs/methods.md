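# Methods

## The mobility index

The unit of analysis is a (user, week) pair, weeks running Monday
through Sunday in UTC. A user's check-ins in a week, C₁ … Cₙ, define a
weekly centroid — the 3-D unit-vector mean of the points mapped back to
latitude/longitude — interpreted as that week's "home". The distance
sequence D assigns each check-in its geodesic distance in km to the
weekly centroid, and the weekly index is the population standard
deviation σ(D) (ddof = 0). The per-user index M averages σ(D) over the
user's N retained weeks.

Two properties motivate the definition. First, it measures dispersion
around a home rather than accumulated path length, so posting frequency
per se does not inflate it: any number of check-ins from one point
scores 0. Second, it is invariant to the within-week ordering of
check-ins, so irregular posting times do not matter.

Distance-to-centroid was chosen over consecutive-pair distances
(both readings are defensible for this family of statistics) because it
matches the centroid-as-home framing, yields exactly one distance per
check-in, and makes the index a measure of travel *area and regularity*;
the consecutive-pair variant is not implemented.

The population (rather than sample) standard deviation is used because
it is well defined at the minimum retained week size n = 3 and the index
is a descriptive dispersion, not an estimator of a population variance.

## Location resolution

Input events mirror the public Twitter JSON subset: an optional
`coordinates` pair ([lon, lat], GeoJSON order) and an optional `place`
object with a type (poi, neighborhood, city, admin, country), a name, a
country code and a bounding box. Exact coordinates always win and are
passed through bit-identically. A place resolves to the midpoint of its
bounding box's lon/lat extents — places are small rectangles, so the
midpoint and the true areal centroid are indistinguishable; boxes
spanning the antimeridian are rejected rather than silently mis-centred.

Place handling depends on the analysis level. POI and neighborhood
places carry only a country in their metadata, so their state cannot be
recovered without an external lookup: state-level analyses exclude them.
City-level analyses keep a POI/neighborhood only when the configured
city name appears (case-insensitively) in the place name, or when the
place id is explicitly whitelisted — the whitelist is how the five New
York City boroughs are merged into one city. National analyses keep
every place type. An optional country filter drops events whose place
country differs from the configured code, since bounding-box stream
collection leaks neighboring countries.

## Filters

Three sparse-data rules, applied in this order:

1. week exclusion: with at least 4 weeks of totals, a week whose user
   count *or* record count falls below mean − z·sd of the respective
   weekly series is treated as a collection failure and removed
   everywhere; z = Φ⁻¹(0.9975) ≈ 2.807, a one-sided lower normal limit.
   The two count series are screened independently because either
   signal alone indicates data loss.
2. users with fewer than 3 resolved check-ins overall are dropped;
3. user-weeks with fewer than 3 check-ins are dropped (σ of one or two
   points is degenerate or trivially small).

N counts only weeks surviving both filters. The all-time centroid used
for region assignment is computed over *every* resolved event of a
retained user, including events in dropped weeks — a thin week still
says where the user was.

## Region assignment

Each user is assigned once, from their all-time centroid, by
point-in-polygon against the supplied GeoJSON regions (boundary points
count as inside). A centroid on a shared edge goes to the
lexicographically smallest region id, a pure determinism tie-break.
Per-week reassignment is deliberately not done; a user who moves during
the study is attributed to one region throughout. Invalid polygons are
rejected at load time.

## Reduction metrics

The study window splits at a configurable date (default 2020-03-16;
before-period start 2019-01-01, after-period end 2020-04-27).

* **Group level**: 100·(m_b − m_a)/m_b where m_b, m_a are the means of
  all retained user-week indices of the region in each period. A zero
  before-mean yields null with a warning. Regions are ranked by this
  number (1 = largest drop, ties by region id); an aggregate row over
  all assigned users is reported unranked.
* **User level**: the same formula on the user's per-period mean index,
  over "active" users — at least two resolved check-ins in each period.
  The activity threshold counts raw check-ins, not retained weeks,
  because two check-ins demonstrate presence while remaining below the
  weekly retention filter. An active user with check-ins but no
  retained week in a period has no measurable travel and contributes a
  period index of 0. A user with index 0 before and positive after has
  no finite percentage; they are reported null and excluded from
  medians (but still counted as active). "Complete reduction" means
  after-index exactly 0 with a positive before-index; the reported
  fraction is over all active users.
* **Seasonal**: identical to user level with the before window replaced
  by the same calendar dates one year earlier, controlling for seasonal
  travel; users without coverage in the reference window drop out.

## Daily series and change points

The daily series applies the same σ-of-distances statistic per user to
a trailing 7-day window of points (≥3 points required), then averages
users per day. The trailing (not centered) window keeps the series
causal; the first 6 days of a range are not emitted. Averaging per-user
daily indices (rather than smoothing weekly regional means) is the
default ordering because it mirrors the weekly construction; the window
length and minimum points are parameters.

Change points are found by L2-cost binary segmentation: a split is
accepted greedily while the reduction in within-segment sum of squares
exceeds a penalty. Default penalty is σ̂²·log T with
σ̂ = median|Δx|/(√2·0.6745), a robust noise estimate from first
differences; minimum segment length is 7 days so week-scale periodicity
is not chased. All knobs (penalty, minimum segment, maximum number of
points) are exposed, and detection is fully deterministic. On noiseless
piecewise-constant input the detector provably coincides with
exhaustive SSE search for the first split; the tests verify this and
the ±3-day localization rate on noisy two-step series. Note the 7-day
moving average correlates adjacent samples, so the first-difference
noise estimate is biased low and the detector errs toward reporting
extra points on smooth ramps; interpret counts, not just positions,
with that in mind.

The "stationarity" comparison uses a deliberately simple, documented
score — variance of first differences divided by the squared segment
mean — rather than a named unit-root test, because the comparison is
between a prefix and the full series of the same signal, where a
scale-free volatility ratio is the interpretable quantity.

## Correlation analyses

Daily infection rate is new cases over population per region-day. For
each day, Pearson r is computed across regions between the rate and a
static covariate, with pairwise-complete deletion; days with fewer than
3 paired regions or zero variance yield null. The policy analysis
correlates cumulative cases at a reference date with the policy's age
in days; regions that never announced a policy receive a −1000 sentinel
so absence itself carries (strong, deliberately off-scale) signal — the
sensitivity of r to the sentinel value is real and tested, not hidden.
p-values use the standard two-sided t approximation for Pearson r.

## Geodesy

Distances use Vincenty's inverse formula on the WGS84 ellipsoid,
vectorized over numpy arrays, with endpoints put in a canonical order
first so the computation is exactly symmetric. Agreement with an
independent Karney-type implementation is at the 10⁻¹⁰ km level on
continental-scale test pairs; the rare non-converging near-antipodal
pairs (≳19,900 km, irrelevant at mobility scale) fall back to the
spherical great-circle distance. A haversine is provided as a documented
fast approximation and is never the default. Weekly dispersions below
10⁻¹² km (float-cancellation residue when all points coincide) are
snapped to an exact 0 so "no travel" and "complete reduction" are exact
statements.

## Synthetic data generator

The generator emulates the statistical structure the index assumes:
each user has a fixed home drawn uniformly inside a fixture region
polygon; check-ins arrive Poisson(λ/7) per day; each check-in displaces
from home by an isotropic bivariate normal in the local tangent plane
(degree/km small-angle mapping), with scale σ_pre before the
regime-change date and σ_post on/after it (the regime switches at the
UTC day boundary). A configurable fraction of events carries exact
coordinates; the rest carry a small place box that contains the true
point but whose center is jittered, so place-resolved positions are
quantized like real place check-ins. Streams are byte-identical under
the same seed.

Defaults define the standard study conditions: 2,000 users, λ = 10
check-ins/week, σ_pre = 30 km halving to σ_post = 15 km at 2020-03-16,
8% exact-coordinate share, 0.02° place boxes, two 1°-square fixture
regions. The 12-week window (2020-02-03 to 2020-04-26, six weeks per
regime) is the package's chosen problem size for recovery experiments:
long enough that per-period means are stable, small enough to iterate
on. With ~24,000 retained user-weeks per run the sampling error of the
group reduction is ≈0.2 percentage points.

What the generator does *not* emulate — bursty and diurnal posting,
users moving house, heavy-tailed trip lengths, bots, demographic
selection into geotagging — bounds what passing tests show: they
demonstrate that the pipeline recovers planted dispersion changes under
the model's own assumptions, not that the index is unbiased on real
feeds.

Two Monte-Carlo oracles accompany the generator, both simulating the
displacement law directly in the plane (independently of the geodesic
and pipeline code): the expected weekly index at given (σ, n), and the
expected group reduction under Poisson week sizes conditioned on
passing the retention filter, with a delta-method standard error.

## Known limitations

* Week/day boundaries are UTC; local-midnight effects shift events near
  boundaries for users far from Greenwich.
* The index conflates fewer check-ins with less travel by construction
  (a week of 3 identical points scores 0 regardless of unobserved
  travel); this is a property of the statistic, not a bug.
* Place-center quantization adds sub-box-scale noise to place-resolved
  events; with the default 0.02° boxes this is ~1 km, negligible
  against 15–30 km travel scales but visible if σ is set comparable to
  the box size.
* Binary segmentation is greedy; for series with many close change
  points an exact dynamic-programming segmentation would differ.
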
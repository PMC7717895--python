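# geomobility

Travel-dispersion surveillance from geolocated social-media check-ins.

Public geotagged posts are a free, continuously updated record of where
people are. During an epidemic, aggregating them answers a question
health agencies care about: *did people actually reduce their travel
when social-distancing policies were announced, and by how much, where?*
`geomobility` implements a per-user, per-week **social mobility index**
over such check-in streams, together with the full analysis pipeline
around it — location resolution, sparse-data filtering, regional
aggregation, before/after reduction metrics, daily moving-average
series, offline change-point detection, and correlation analyses — plus
a synthetic check-in generator with known ground truth so every stage is
testable without any platform data.

## The statistic

For a user with check-in coordinates C₁ … Cₙ inside one Monday-start
week (UTC), let the weekly centroid (the "home" for that week) be the
normalized 3-D mean of the points, and let

&nbsp;&nbsp;&nbsp;&nbsp;Dⱼ = geodesic distance (km, WGS84) from Cⱼ to the weekly centroid.

The weekly index is σ(D), the population standard deviation of the
distance sequence, and the user's mobility index is

&nbsp;&nbsp;&nbsp;&nbsp;M = (1/N) Σᵢ σ(Dᵢ)

over the N retained weeks. The index measures the *area and regularity*
of travel rather than raw distance traveled: a user posting from one
point all week scores exactly 0 km, a commuter scores the spread of
their commute, and a long one-off trip scores large. Regional series
take the mean of user indices per week; the group-level reduction
between a "before" and an "after" period is
100·(mean_before − mean_after)/mean_before.

Sparse-data rules: users with fewer than 3 check-ins overall and
user-weeks with fewer than 3 check-ins are dropped; weeks whose total
user or record count falls below a one-sided 99.75% lower normal limit
of the weekly counts (collection failures) are excluded everywhere.

## Worked example

A self-contained run on simulated data — 2,000 users with homes in two
square fixture regions, Poisson(10) check-ins per week, isotropic travel
whose scale halves from 30 km to 15 km at the regime-change date
2020-03-16:

```sh
geomobility run --simulate demo --seed 1 --outdir out/
```

`out/reduction_report.csv` (excerpt, values from this exact command):

```
region_id,mobility_before_km,mobility_after_km,group_reduction_pct,median_user_reduction_pct,...,n_active_users,rank
A,16.74,8.41,49.75,49.48,...,972,2
B,16.82,8.36,50.30,50.27,...,959,1
ALL,16.78,8.39,50.02,49.84,...,1931,
```

Reading the numbers: the mean weekly index before the regime change is
≈16.8 km (for isotropic displacements of scale σ = 30 km and Poisson(10)
weekly check-in counts the expected index is ≈0.56·σ), it halves after,
and the recovered group-level reduction of ≈50% matches the planted
halving of the travel scale within sampling error. Ranks order regions by group reduction; the aggregate row `ALL`
is unranked. The directory also contains the per-user weekly indices,
regional weekly series, the 7-day moving-average daily series, and the
change points detected on it.

Stage-wise CLI equivalents: `geomobility simulate | ingest | index |
reduce | changepoints | correlate` (see `--help` on each).

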
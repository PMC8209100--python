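# Methods

`walkpulse` implements a walking-behavior surveillance pipeline for
anonymized smartphone GPS panels: bout detection, trip-purpose
classification, panel aggregation with post-stratification, and an
area-level inequality regression.  Because real commercial mobility
panels are licensed and not redistributable, the package ships a
synthetic world and trace generator with known ground truth; every
guarantee the test suite states is a recovery property against that
ground truth.

## Walk-bout detection

A *walk bout* is a maximal run of consecutive pings of one user in
which every consecutive pair satisfies

* pair speed ≤ `speed_threshold_mps` (default **2.0 m/s**, boundary
  inclusive — a pair moving exactly at the threshold is walkable),
* pair time gap ≤ `max_ping_gap_s` (default **180 s**),
* pair time gap > 0 (a zero gap has infinite speed, never walkable).

Distances are great-circle on a sphere of radius **6371.0088 km** (IUGG
mean radius); no projection is assumed for metric quantities.  Candidate
bouts need ≥ `min_pings_per_bout` pings (default 2) and a summed
distance ≥ `min_bout_distance_m` (default **50 m**; "less than 50 m" is
discarded, the boundary kept) — the 50 m floor is the guard against GPS
jitter masquerading as movement.  Finally a bout must lie in
*pedestrian-eligible space*: every ping within `pedestrian_buffer_m`
(default **20 m**) of a pedestrian-class road segment (secondary,
tertiary, residential, living street, pedestrian, footway, track, path
— not motorways/trunks, where congestion crawls at walking speed) or
inside a park polygon.  The all-pings quantifier is the strictest
reading; a fractional rule (`pedestrian_rule="fraction"`) is available.

The temporal gap bound is not part of the classic speed-threshold rule
but is necessary: without it, two slow pings hours apart would fuse
into one "walk".  180 s is three missed reporting cycles at the
generator's 60 s cadence; it is configurable.

Point-to-segment distances for the buffer test run in a local
equirectangular plane centred on the layer origin; over a metropolitan
extent the planar error is millimetres against 20 m buffers.  Spatial
indexes are shapely STRtrees, and the test suite proves index/brute-
force equivalence exactly.

Bouts are assigned to the local calendar date of their first ping
(bouts spanning midnight count toward the day they started); local time
uses a per-run IANA timezone.

## Purpose classification

Walking splits into *utilitarian* (errands, transport legs, work) and
*leisure* (walking for its own sake).  The operational rule:

* distance ≤ `distance_threshold_m` (default **750 m**, boundary to
  utilitarian) → utilitarian;
* longer bouts are judged by destination: the POI nearest to the final
  ping within `poi_match_radius_m` (default **25 m**, great-circle,
  ties to the lowest POI id).  No POI, or a POI in
  `leisure_categories` (default `{city/outdoors}`, which includes
  residential space) → leisure; any other category → utilitarian.

Only the final ping is probed; intermediate POI passes are ignored.
The threshold and radius are exposed for sensitivity analysis
(rerunning at 500/750/1000 m is a tested harness).

## Panel aggregation

*Home tract* is the modal tract of a user's local-nighttime
(22:00–06:00) pings, falling back to the modal tract of all pings; ties
break to the smallest tract id.  *Post-stratification weights* correct
panel non-representativeness: `w(user in tract α) = (pop_α/Σpop) /
(devices_α/Σdevices)`, normalized to mean 1, so the weighted device
share per tract equals the population share by construction.

Per-user-day summaries contain explicit zero rows for every *active*
user-day (≥ 1 ping that local day); per-day panel averages are weighted
means over active users.  On top of the summaries the package computes
weekly engagement (fraction with ≥ 1 bout, ≥ 10 walking minutes, mean
bouts/user/day, and the activity-guideline fraction — ≥ 30 min on ≥ 5
distinct days), 24×7 hour-by-weekday bout matrices, pre/post relative
changes `100·(mean_post − mean_pre)/mean_pre` by panel, tract, purpose
or attribute quintile, and daily quintile series where tracts are
ranked by an attribute and cut into five groups holding ≈ 20% of
population each (tract-count cuts are a config switch).

## Inequality model

Tract-level outcome: weighted mean meters walked per person per day,
separately pre and post intervention (tracts with < 5 users excluded).
Covariates — median income, fraction Black, fraction public-transit
users, fraction over 64, park access, obesity prevalence — are z-scored
over the estimation sample (n−1 denominator), so coefficients read as
meters/day per SD.  The metropolitan area enters as a fixed factor
(indicator variables, reference = lexicographically first MSA); since
the model contains only fixed terms it is fit as OLS with classical
standard errors, delegated to statsmodels.  The fit is unweighted by
population (a weights switch exists).  Reported: coefficients (SE),
significance stars (p < 0.1 / 0.05 / 0.01), intercept, MSA effects, R²,
adjusted R², residual SE with df, F statistic, and a pre/post
comparison table.  Fixed-effect slopes are verified against the
within-MSA demeaned regression to 1e-8.

## Synthetic world and traces

The toy world is a planar grid street network (spacing 250 m over a
6 km extent by default) projected to WGS84 around a configurable
origin, with pedestrian classes cycling over the grid lines, motorways
offset half a spacing (so their traffic is > 20 m from walkable
streets), square parks covering ≈ 5% of area, POIs placed on pedestrian
segments with a configurable category mix, and census tracts tiling the
extent, assigned round-robin to MSAs.

Users get a home (≥ 25 m inside a tract, near a street node) and emit:

* **stationary nights** — jittered pings at home every 600 s during
  local 22:00–06:00.  Idle devices report sparsely; this cadence also
  means stationary runs are broken by the 180 s gap rule rather than
  accumulating phantom jitter path (pure 2-D jitter of sd σ adds ≈ σ·√π
  meters of false path per ping pair, which no distance filter could
  reject at a dense cadence);
* **walks** — routed along the pedestrian grid at U(0.7, 1.4) m/s.
  Utilitarian walks are 100–700 m and end exactly at a non-outdoors
  POI; leisure walks are 850–2500 m and end ≥ 60 m from any POI.
  Utilitarian bout counts are Poisson(0.4)/user/day before the
  intervention and are multiplied by 0.3 after it; leisure counts stay
  Poisson(0.12) throughout (the planted differential shock).  The
  resulting panel walks ≈ 0.52 bouts/user/day pre-intervention with
  ≈ 77% utilitarian, and mean planted lengths ≈ 400 m (utilitarian) and
  ≈ 1675 m (leisure) — magnitudes typical of US metropolitan panels;
* **drives** — Poisson(0.3)/user/day along motorway lines at
  U(6, 15) m/s.

Pings are emitted every 60 s along each planted path with isotropic
Gaussian noise (sd 3.5 m) and always include the exact path endpoint;
the final inter-ping gap spans [60 s, 120 s) so endpoint noise cannot
manufacture a fast pair.  These choices keep measured pair speeds on
the correct side of 2 m/s with ≥ 7σ margin, making the planted labels
recoverable — by design the generator realizes the separability the
detection rule assumes.  Utilitarian start times are bimodal
(≈ 07:30/16:00 weekdays, midday weekends) so the hour-by-weekday
matrices have recoverable structure.

Tract attributes come from a correlated Gaussian copula (default
|r| ≤ 0.5, e.g. income–obesity −0.45) mapped monotonically to plausible
units; the planted outcome is `Σ βj·z(xj) + MSA intercept + N(0,
noise_sd)` on the empirical z-scores of the final covariates, so the
planted coefficients are exactly identified.  Default β (meters/day per
SD): income −29.205, Black 2.745, public transit 54.170, over-64
−0.331, park access 15.691, obesity −20.703; reference intercept
315.572 m/day and default noise sd 100 m — magnitudes chosen to match
published area-level walking gradients.

### What the generator does and does not emulate

It emulates the statistical skeleton the analysis assumes: speed-
separable travel modes, POI-anchored destinations, jittered sparse
stationary periods, a differential behavioral shock, representativeness
error between devices and population, and a linear area-level outcome
structure.  It does **not** emulate GPS urban-canyon multipath, transit
or cycling modes, route choice, activity scheduling beyond independent
Poisson counts, within-tract heterogeneity of behavior, or any coupling
between tract covariates and individual walking.  Passing tests
therefore certify that the pipeline recovers what its rules define on
data satisfying its assumptions — not that the rules are correct for
any particular real panel.

## Numerical choices and degenerate inputs

* Great-circle radius 6371.0088 km everywhere; planar operations only
  for point-in-polygon and point-to-segment tests in a local frame.
* Speed boundary inclusive (≤), distance floor inclusive (≥ 50 m kept),
  POI radius inclusive (≤ 25 m), purpose boundary 750 m → utilitarian.
* Zero time gaps → infinite speed; zero-variance covariates and
  rank-deficient designs are errors naming the offending column;
  zero pre-period means make relative change undefined (missing, with
  a warning); constant attributes collapse quintiles to one group with
  a warning; empty worlds fail the pedestrian test for all bouts with
  a warning.
* Sample sd uses n−1 throughout; weighted means use Σwx/Σw.
* The pipeline fans a single seed into per-stage seeds by fixed
  offsets; identical config + seed reproduces byte-identical outputs.

## Problem sizes in the shipped checks

The demo panel is 200 users × 120 days (≈ 1.35 M pings, ≈ 8 300 bouts),
sized so the full chain runs in a couple of minutes on one CPU.
Regression recovery uses 9 000 tracts for the single-fit check and
100 replicates of 400 tracts for interval coverage.  Segmentation is
verified against a brute-force reference on 10 000 random streams and
spatial queries against linear scans on 1 000 random points.

## Known limitations

* Chord sampling between 60 s pings shortens measured path lengths at
  street corners (worst case 1/√2 of the planted length); detection and
  classification margins account for this, but absolute distances are
  mildly underestimated relative to planted truth.
* The pre/post relative-change estimator inherits Poisson counting
  error from bout counts: with ~24 leisure bouts/day panel-wide and
  month-long windows its sampling sd is ≈ 5 percentage points at the
  200-user demo scale; detecting small changes requires a larger panel
  (the estimator is unbiased — see the acceptance script, which sizes
  the panel to the tolerance it checks).
* Post-stratification corrects only tract-level device counts, not
  within-tract selection.
* The fixed-effects model is descriptive; no spatial autocorrelation
  adjustment or causal identification is attempted.
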
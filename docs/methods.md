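# Methods

## Problem

An instrumented marine animal is a mobile sampling platform: wherever it
goes, its tags record the environment (here, coded 69 kHz acoustic
transmissions from tagged fish). Because the platform chooses its own
itinerary, sampling is non-random in space and time, and any quantity
derived from the recordings must be normalized by where and for how long
the animal actually sampled. This package quantifies that sampling
coverage at three levels: a single animal's utilization distribution,
the pooled coverage of many animals through the season, and the rate of
acoustic transmissions received per unit sampling effort.

## Time-scaled local convex hulls

For a track of n projected GPS fixes, the time-scaled distance between
fixes a and b is

    TSD(a, b) = sqrt(dx^2 + dy^2 + (s * v_max * dt)^2)

where dx, dy are the planar separations in metres, dt the time
separation in seconds, v_max the maximum speed over consecutive fix
pairs of the track (m/s), and s a dimensionless scaling factor. The
product `s * v_max * dt` is a fraction of the maximum distance the
animal could have covered in dt, mapped onto a third Euclidean axis, so
fixes close in space but far apart in time are pushed apart. s = 0
recovers the purely spatial metric.

Each fix becomes the parent of a hull: the minimum convex polygon of the
fix and its k nearest neighbours under TSD (the k-method). Neighbour
ties are broken by earlier timestamp, then input order, making the
construction fully deterministic. Hulls are sorted by ascending area
(ties by parent timestamp) and cumulatively unioned; the isopleth at
density-quantile level q is the smallest prefix union enclosing at least
`ceil(q n)` distinct fixes, boundary inclusive. The 25 % isopleth
outlines the most intensely used area, the 95 % isopleth the overall
range. By construction isopleths are nested and their areas
non-decreasing in q.

Degenerate hulls — collinear or coincident member points, routine while
the animal is hauled out on land — are kept with zero area and sort
first: they mark maximal point density.

### Parameter choices

* Individual mode: k = 10, s = 0.03. With fixes arriving roughly every
  18 min at the surface, a 10-neighbour hull standardizes each polygon
  to about a 3-hour window of movement. s = 0.03 is the value at which
  roughly 60 % of hulls become *time-selected*, i.e. their TSD neighbour
  set differs from the purely spatial one; `fraction_time_selected`
  evaluates this over all hulls.
* Collective mode: k = 5, s = 0. Pooled fixes from different animals
  carry no meaningful joint trajectory, so time is excluded, and the
  smaller k (a ~90-min window) keeps hulls conservative against
  swallowing unused area.
* Quantile levels default to 25/50/75/95 %.
* `edge_area_diagnostic` reports area and perimeter:area by quantile
  over a k grid, to verify the chosen k sits below any sudden jump in
  area.

### Occupancy time

The hull metric "time the polygon was occupied" has no closed
definition at fix level; we use a visit-run rule: enclosed fixes are
split into maximal runs consecutive in the owning animal's own track
order; each run contributes its elapsed time, and a single-fix run
contributes one nominal surfacing interval (18 min) so that a brief
pass never counts as zero. On pooled tracks, runs are per animal and
summed — collective occupancy is collective time spent in the area.
For a single-animal pool this reduces bit-for-bit to the individual
definition.

## Collective coverage by month

Fixes from all animals are pooled and stratified by UTC calendar month.
Per month the package reports, per quantile level: isopleth area (km²),
time-at-sea (the count of at-sea fixes inside the isopleth — fixes
arrive every ~18 min at sea, so the count is a time proxy), and the
equal-use null area `(q / 0.95) * area(0.95)`, the area expected if all
parts of the range were used evenly. Hauled-out fixes are retained in
hull construction by default (they genuinely outline the colony) but
excluded from time-at-sea; the `at_sea` flag supports either choice.

Note the equal-use null is a reference line, not a fixed point of the
estimator: even on homogeneously scattered points the cumulative-merge
construction yields 25 %-level areas well below q/0.95 of the 95 % area,
because a k-neighbour hull always encloses at least k+1 fixes within
less than those fixes' density share of area, so point coverage
accumulates faster than area. Observed/expected ratios should therefore
be compared between months or against a concentrated-use alternative,
not read as absolute departures from 1.

## Acoustic reception and TPUE

Receiver clocks are synchronized at deployment and drift linearly;
`correct_clock_drift` removes `rate * (t - t0)` with the rate estimated
from the measured offset at retrieval divided by the deployment length
on the tag's own clock, anchoring the corrected timeline exactly at
both ends (residual curvature is O(rate²), sub-millisecond over a
half-year deployment).

Each received ping is classified by its interval to the previous ping:
below 0.26 s unclassifiable noise; 0.26–0.29 s echo/multipath;
0.30–0.70 s consecutive pings of one transmission; 0.71–1.50 s one or
more skipped pings; above 1.50 s spurious or three-plus skipped.
Bounds are closed at the printed 2-decimal precision, so the classes
tile the axis. Assembly walks the classified stream: consecutive and
skipped intervals extend the current run, echoes attach without
counting, noise and spurious intervals break runs, and runs split after
the 8th ping. A transmission is *complete* only at exactly 8 pings;
partial runs are retained and counted by default, since environmental
conditions make full 8-ping receipt rare.

Transmissions are matched to the nearest-in-time GPS fix (ties to the
earlier fix; beyond 30 min, two nominal surfacing intervals, the
transmission is left unmatched). Matching against the raw fixes is the
default; a 15-min linearly interpolated grid (suppressed inside gaps
longer than 2 h) is available via configuration. The matched fix is
assigned to the smallest-area hull containing it and to the smallest
isopleth level containing it ("outside" if beyond the largest).

Per receiving polygon, sampling effort is `area_km2 / occupancy_h`
(km²/h) and TPUE is `n_transmissions / effort = n * t / A`. Zero-area
degenerate polygons have undefined effort; their records are flagged
and excluded from summaries. Quantile summaries report transmission
counts and mean ± SE (sample sd / sqrt(n polygons)) of area, occupancy
and TPUE, with SE undefined below two polygons.

## Synthetic deployments

The generator emulates the study system so the full pipeline can be
exercised end to end:

* Movement: a central-place forager alternating colony haul-outs
  (uniform 14–40 h) with trips to weighted offshore hotspots. Transit
  is a correlated walk at 1.4 m/s with heading noise (sd 0.25 rad);
  dwell inside the hotspot is a bounded wander, with dwell duration set
  so each hotspot's share of at-sea time matches its weight (the
  in-radius tail of the transit is deducted from the dwell budget).
* GPS sampling: at-sea inter-fix intervals are gamma distributed with
  mean 17.92 min and sd 3.92 min (the gamma matches both stated moments
  on positive support); fixes carry 15 m isotropic noise. Haul-outs
  emit a fix at entry and then one per 8 days while the haul-out
  exceeds 12 h, scattered 400 m around the colony.
* Acoustics: moored transmitters emit 8-ping transmissions every
  40–60 s with inter-ping intervals uniform on 0.30–0.70 s. Reception
  is a hard range cutoff — the range drawn per transmission uniformly
  between 482.4 m (roughest conditions) and 750.4 m (calmest) — plus
  independent per-ping Bernoulli loss (default 0.1). Background noise
  is a Poisson ping stream; the receiver clock drifts linearly
  (default 0.2 s/day). A ground-truth table records every emitted
  transmission for end-to-end scoring.

Everything derives from `numpy.random.default_rng` seeded by the
configured seed plus a CRC of the stream name and animal id, so output
is byte-identical under a fixed seed and independent across animals.

What the generator does not emulate: dive profiles (reception is judged
at the interpolated surface position), oceanographic detection-range
variation beyond the per-transmission draw, tag collisions between
simultaneous transmitters, and GPS fix failure in rough weather.
Passing recovery tests therefore shows the pipeline is internally
consistent and sensitive at realistic signal levels, not that field
data would be this clean.

## Numerical choices

* Geometry runs entirely in a projected metric plane; the default CRS
  is UTM zone 20N via an in-package WGS84 transverse-Mercator transform
  (classical series, sub-metre accuracy inside a zone), and GeoJSON
  output is reprojected to WGS84 after areas are computed.
* Exact k-NN by full distance sort (no spatial index): tracks at desk
  scale are a few thousand fixes, and the deterministic tie-break is
  worth more than the asymptotic speedup.
* Timestamps are nanosecond integers internally; differences are taken
  on the integer values (`Timedelta.total_seconds` floors at
  microseconds and is asymmetric for negative deltas).
* Point-in-polygon is boundary-inclusive everywhere (`shapely.covers`).
* Problem sizes in tests: tracks of 40–200 fixes for oracle comparisons,
  1,000 points for the homogeneous-null measurement, 10–20 day single-
  animal deployments for recovery runs. These sizes give stable
  statistics while keeping the whole suite fast.

## Known limitations

* Isopleth area at low quantile levels is a biased-low estimator of
  "share of range used" (see the equal-use note above); comparisons
  should be relative.
* TPUE is computed per polygon and summarized per quantile; with few
  transmissions per polygon the SE is wide, and polygons receiving no
  transmissions contribute no effort record (reception-conditioned
  sampling).
* The transverse-Mercator series degrades beyond ~±4° of the central
  meridian; tracks spanning multiple UTM zones should be projected
  zone-by-zone.
* Month stratification splits a trip that crosses a month boundary;
  hulls never span months.
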
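# Methods

## Problem setting

GPS cluster studies direct field crews to places a collared animal
concentrated its activity. The analysis must be *repeatable* (same
parameters, same clusters, season after season) and *incremental* (new
fixes arrive every day or few days; IDs already written on datasheets must
not move). This package implements that workflow as a library plus CLI.

## Clustering model

Fixes of one animal are nodes of a graph with an edge whenever the planar
Euclidean distance between two fixes is at most `2 * buffer_m` — the
condition for two discs of radius `buffer_m` to overlap. The comparison is
inclusive: tangent buffers count as overlapping. Default-mode clusters are
connected components with at least `min_locations` members; the transitive
closure means a cluster's spatial extent can exceed `2 * buffer_m`.
Consecutive-only mode instead takes maximal runs of time-adjacent fixes
with every adjacent pair linked; it separates spatially coincident but
temporally distinct visits (e.g. a revisit to an old kill) into different
clusters, or into none.

Clustering is strictly per animal: cluster IDs embed the animal ID, and
pooling animals would make ID persistence ill-defined. Neighbor pairs come
from `scipy.spatial.cKDTree.query_pairs` feeding a union–find; the test
suite and the acceptance script verify the resulting partition against an
independent O(n²) connected-components oracle on random instances.

### Numerical choices

* Distances are planar meters in a projected CRS declared by
  `crs_epsg`; ingest enforces this (geographic sources are projected).
  Geodesic distances were rejected: buffers in GIS practice are planar,
  and study areas are small relative to the ellipsoid.
* Buffer circles are approximated by 32-segment regular polygons
  (shapely `quad_segs=8`); the inscribed-polygon area deficit is ~0.64 %,
  within the 1 % documented tolerance.
* Tangent discs (centers exactly `2 * buffer_m` apart) touch in one
  point; a morphological closing with a sub-millimeter epsilon welds the
  contact so a valid cluster is always a single-part polygon.
* Cluster sequence numbers are assigned per animal by first visit time,
  ascending. Ties are impossible because (animal, timestamp) pairs are
  unique after validation and a fix belongs to exactly one cluster.

### Summaries

`n_outside` counts the animal's non-member fixes with timestamps inside
the cluster's closed visit window `[first_time, last_time]`, and
`percent_time = 100 · n_inside / (n_inside + n_outside)` is a *fix-count*
share, not an elapsed-duration share. Under a regular fix schedule the two
coincide; under an irregular one the fix-count version is the only
quantity the data support without interpolation, and it pairs naturally
with the inside/outside counts shown next to it. This choice is a
documented convention.

### Point IDs

`<animal>_<C{seq}|SP>_<MMDDHH>` with zero-padded month, day and hour
(`SP` = single point). Collisions within one animal-hour get the
zero-padded minute appended to every collider, and any remainder a running
lowercase letter in timestamp order. The exact delimiter and padding are
this package's convention, chosen for lexicographic sortability.

## Preprocessing

Pipeline order is fixed: validate (sort, drop non-finite coordinates,
collapse duplicate (animal, timestamp) rows keeping the first) → closed
study-period filter (a timestamp equal to either bound is inside; "May 1
to May 31" includes both days) → z-minute subsampling. The subsampler is
greedy from each animal's first in-period fix: keep a fix when it is at
least z minutes after the last kept fix. Greedy-from-first is
deterministic, idempotent, and guarantees output gaps ≥ z, which is what
is needed to neutralize proximity-burst oversampling; anchoring at the
nominal schedule grid instead was considered and rejected because the
grid is not observable from the data when collars drift or reprogram.
`z = 0` (the default) keeps every fix.

## Incremental re-analysis

A subsequent analysis recomputes clustering on the *full* (old + new) fix
set under the identical parameters and then relabels from the previous
run, rather than growing frozen previous polygons. Because clustering is
deterministic, this single code path makes incremental output exactly
equal to a batch run on the same data — the property the acceptance suite
checks over random time splits.

Matching: every previous cluster's member set is, with unchanged
parameters and appended data, wholly contained in exactly one recomputed
cluster (components only grow; consecutive runs only extend). Member
identity is the (animal id, timestamp) pair, which is stable; the literal
Point-ID string is not a usable key because its cluster-number token
changes when clusters merge. Outcomes:

* identical member set → **kept** (ID and state carried over);
* superset of one previous cluster → **grown** (same ID, state `Grown`);
* superset of several → the **lowest previous sequence number survives**
  (oldest site under first-visit numbering), the others are recorded as
  absorbed and their editable columns are concatenated into the survivor's
  notes. Which ID should survive a merge is not dictated by the workflow
  itself; lowest-seq is this package's documented convention, with the
  reconciliation report preserving full traceability;
* no previous members → **new**, numbered from (per-animal max previous
  seq) + 1, so absorbed numbers are never reused.

Changing any clustering-relevant parameter between runs raises an error:
clusters produced under different parameters are not comparable, and the
whole point of the settings sidecar is to prevent silent drift. A fix file
missing members of a previous cluster (truncated download) is likewise an
error rather than a silent re-numbering.

## File formats

Cluster layers are GeoJSON polygon FeatureCollections carrying the full
attribute table plus the member point-ID and member-timestamp lists needed
for reconciliation; coordinates are written at full float precision, so a
write → load cycle reproduces vertices to well under 1e-6 m. The settings
sidecar is plain `key = value` text (diff-friendly, readable in the
field). "Latest previous analysis" is resolved by the sidecar's
`analysis_time`, never by file mtime, so copying a season's outputs
between laptops cannot reorder history. CSV ingest assumes coordinates
already in the study CRS; GeoJSON ingest (WGS84 by specification) is
reprojected.

Projection between WGS84 and the UTM study CRS (needed for GPX waypoints
and geographic export) is a fourth-order Karney–Krüger transverse-Mercator
series implemented in `crs.py`, supporting EPSG 32601–32660 / 32701–32760.
Truncation error is below 0.1 mm inside a zone; the tests verify the
central-meridian northing against a numerically integrated meridian arc
and round-trip all transforms to 1e-9°. GPX output is GPX 1.1 with the
`wpt` children in schema order; tests validate structure (namespace,
version, attribute ranges, element order) with lxml.

## Synthetic data generator

The generator is the package's ground-truth source. One animal's track
alternates between:

* **stationary bouts** — fixes at a planted center plus isotropic
  Gaussian scatter (`scatter_sd_m`, default 5 m, i.e. typical collar
  error at a carcass);
* **directed transit** — steps of `travel_step_m` (default 500 m per
  hourly fix, a realistic traveling pace for a large carnivore) ×
  uniform(0.8, 1.2), with heading = per-animal base bearing + a wobble
  driven by truncated wrapped-Cauchy turns (ρ = 0.9, |turn| ≤ 22.5°) with
  mean reversion, capped at ±36°.

The wobble cap is the load-bearing choice: it bounds net progress along
the base bearing below by `cos(36°) × 0.8 × travel_step` per fix, so a
transit track is monotone along its bearing and *cannot* re-approach
itself within a 60 m link distance. A free correlated random walk
occasionally reverses and self-intersects, planting spurious two-fix
clusters; with the cap, every cluster in generated data is a planted bout
by construction, which is what makes the recovery and false-positive
properties sharp (exact count equality, zero null clusters) rather than
statistical. The cost is realism: the generator emulates transit legs
between activity sites, not home-range revisitation. Passing tests
therefore demonstrate correctness of the clustering and bookkeeping
machinery, not robustness to tortuous real movement — on real data,
revisits are exactly what consecutive-only mode exists to separate.

**Truth records** count expected cluster members as the number of schedule
ticks inside the bout interval (clustering consumes fixes, not durations).
**Burst episodes** insert fixes between ticks (positions interpolated
along the track, or at the bout center during a bout, plus 5 m jitter); by
construction a 60-minute subsample removes exactly the burst fixes.

The packaged scenario (`scenario_case_study`) is shaped like a spring
predation study: three animals, hourly fixes May 1–31 2014 (UTC), nine
bouts of 12–36 h, one 15-minute-interval burst during a bout, UTM zone
33N. Bout centers are placed ahead of the maximum possible transit
advance between bouts, preserving the no-self-approach guarantee. It is
generated deterministically (internal seed) rather than shipped as a
file; `gpscluster simulate` writes it to CSV.

## Problem sizes used in the verification suites

Oracle agreement: 100 random instances of 50–500 fixes with buffers 5–150
m and minima 2–7. Monotonicity: 50 instances. Incremental equivalence: 10
two-animal, ten-day datasets × 20 random splits each. Recovery/null: 200
scenario replicates each. Subsampling: 50 random schedules. These sizes
make the full acceptance run about a minute on one CPU while covering the
regimes (dense clumps, diffuse scatter, boundary distances) where the
clustering rule has corner cases.

## Known limitations

* Only WGS84 UTM zones are supported for projected↔geographic conversion;
  any projected meter CRS works for clustering itself, but GPX/map export
  then requires UTM.
* Shapefile I/O is not implemented; GeoJSON is the vector format.
* `percent_time` is fix-count based (see above).
* No fix-quality filtering (DOP, 2D/3D) and no gap interpolation.
* Reconciliation requires new data to extend the time series; inserting
  fixes *before* previously analyzed ones can split a previous cluster in
  consecutive mode and is rejected with an explicit error.
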
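# Methods

## Contact-calling procedure

The pipeline consumes identity-linked tracks of two populations — motile T
cells and adherent, fluorescently identifiable target cells — each
observation carrying a segmented outline polygon in micrometres, plus
acquisition metadata (91 frames at one frame per minute by default, so the
final frame index is 90 and "the end of the acquisition" means 90 min).

Stages, in order:

1. **Polygon upscaling.** Binarised fluorescence systematically
   under-covers the true T-cell footprint at its edges, so every T-cell
   polygon is upscaled by a linear factor of 1.002 (0.2 %) about its
   area-weighted centroid before any intersection test. The factor is a
   parameter; 0.2 % is read as a *linear* similarity factor (area grows by
   1.002² ≈ 1.004) anchored at the centroid. The alternative readings
   (areal factor, bounding-box anchor) are reachable through the same
   parameter and transform but are not defaults.
2. **Dead-cell filter.** Tracks with net Euclidean displacement < 15 µm
   (about twice a T-cell diameter) over the whole movie are excluded;
   strict inequality, so a displacement of exactly 15 µm is kept.
3. **Drift filter.** Non-adherent cells carried by flow move in nearly
   straight lines. Persistence is the confinement ratio — net displacement
   over total path length — and tracks with persistence > 0.5 (strict) are
   excluded. TrackMate exposes several straightness-like track features;
   the confinement ratio is the one consistent with passive drifters
   scoring near 1 regardless of speed, and is what this package computes.
   The dead filter runs first, so a track failing both is reported "dead";
   swapping the order relabels but never changes the kept set (asserted in
   tests). Target tracks are never filtered.
4. **Touch detection.** For every frame and co-present (T cell, target)
   pair, a touch is recorded iff the intersection area is at least 10 % of
   the *upscaled* T-cell polygon area of that same frame (the upscaled
   polygon is the object intersected, so it is also the denominator). The
   threshold is inclusive. A T cell may touch several targets in one
   frame. Frames where either track lacks an observation are skipped — no
   interpolation; the gap tolerance below absorbs such dropouts.
   Intersection slivers below 1e-9 µm² are treated as no overlap so that
   floating-point noise at shared edges cannot produce flickering touches.
5. **Contact assembly.** Touches of one (T cell, target) pair are merged
   into maximal runs in which up to 5 consecutive frames may lack a
   qualifying overlap (successive touch frames differ by ≤ 6); a gap of 6
   or more missing frames splits the run. Single-touch contacts are
   allowed.
6. **Classification.** A contact is *end-reaching* iff
   `final_frame − last_touch_frame ≤ max_gap_frames` — the same 5-frame
   flicker tolerance used during assembly, rather than a literal touch at
   frame 90 (requiring the literal final frame is available by setting
   `max_gap_frames = 0`). Among a T cell's end-reaching contacts exactly
   one is *stable*: the longest by duration in frames, ties broken by
   larger cumulative intersection area, then smaller target id (the tie
   rule is a deterministic package choice; only "longest wins" is inherent
   to the method). All other contacts are *transient*. A T cell whose track
   ends more than 5 frames before the final frame can never be stable; its
   contacts are flagged `track_truncated` in the output so such
   tracking-loss cases are auditable.
7. **Per-cell metrics.** Migration statistics (total path length, net
   displacement, mean speed = path/duration, persistence) are computed over
   the full track including contact frames. Targets visited is the number
   of distinct targets a cell contacted, regardless of contact count or
   class. Stopping speed of a stable contact: the reference point is the
   T-cell centroid at the first touch frame (the centroid is the tracked
   position proxy; the method does not prescribe a particular point);
   distances to the reference are recorded for every observed frame up to
   the acquisition end, and the maximum divided by the time to the
   *earliest* frame attaining it gives the stopping speed in µm/s. A cell
   already at its maximum at the first touch gets stopping speed 0 and an
   "instantaneous" flag (not NaN/inf: it is the limiting fast stop, and the
   flag lets it be excluded from averages).
8. **Field and group summaries.** Percentages use the number of cells
   surviving both filters as denominator. The transient percentage counts
   cells with ≥ 1 transient contact; the per-contact count is reported
   alongside because "percentage of transient contacts" is ambiguous
   between cells and contacts. The density factor of a field is its
   activating-target track count divided by the group mean of those counts
   (field area is constant within a group, so counts are proportional to
   density); group mean of factors is exactly 1, and raw stable percentages
   are divided by the factor. Count-based density is the simplest
   operationalisation of "local density relative to the group mean"; an
   area-fraction or neighbourhood-local variant would be a different
   choice, noted as the main normalisation ambiguity. Group tables report
   mean ± sample (n−1) SD only — no inferential statistics.

## Geometry

Area and centroid use the shoelace formulae on counter-clockwise-normalised
simple rings; boolean intersection of general (concave) polygons is
delegated to shapely's clipping engine. Self-intersecting rings are
rejected, not repaired. The test-suite checks clipping against an
independent Monte-Carlo rasterization oracle: one uniformly jittered point
per cell of a regular 10⁵-cell grid over the bounding-box overlap,
classified by a pure-numpy crossing-number test — unbiased, with variance
confined to boundary cells, giving ≲0.2 % relative error on µm²-scale
overlaps.

## Synthetic fields

The generator emulates the statistical structure the analysis assumes, not
the imaging physics:

* **Monolayer.** Uniform seed points in the field (default 400 × 400 µm at
  1600 cells/mm², i.e. ~25-µm cells), relaxed by two Lloyd iterations into
  a near-centroidal Voronoi mosaic of convex tiles. Each tile is
  independently activating with probability 1/16 (the 1:15 mix); only
  activating tiles are emitted as target tracks, because non-activating
  monolayer cells carry no fluorescent label and are invisible to the
  analysis. Targets are static (adherent), with optional sub-micron jitter
  (default 0).
* **T cells** (default 60/field). Migrators perform a persistent random
  walk: per-frame speed ~ Normal(8, 3) µm/min truncated at zero, heading
  rotated by a wrapped-normal deviate with mean resultant length equal to
  `turn_persistence` (default 0.7, σ = √(−2 ln ρ)), rigid regular-16-gon
  footprint of radius 3.75 µm (7.5-µm cell), reflective field boundaries.
  These kinematic defaults are plausible magnitudes for T cells on
  fibronectin, chosen once as generator conditions — they are not measured
  constants. On every frame where the footprint overlaps an activating
  target by ≥ 10 % of its area the cell arrests forever with probability
  `p_arrest_per_encounter` (first Bernoulli success); on arrest it settles
  ≤ 1.5 µm toward the target centroid (deepening the overlap, as a
  spreading cell would) and thereafter jitters ≤ 0.3 µm. Planted dead
  cells jitter ≤ 1 µm in place for the whole movie; planted drifters move
  ballistically at 8 µm/min (persistence ≈ 1). An optional per-observation
  dropout probability exercises the gap tolerance.
* **Randomness.** A seed tree rooted at `config.seed`: one stream for the
  mosaic, one for class assignment, and three per T cell (motion, arrest,
  dropout). This makes exports bit-reproducible and couples runs that
  differ only in `p_arrest`: with common random numbers the arrested set at
  a higher arrest probability is a superset of the set at a lower one, so
  monotonicity checks are exact rather than statistical.
* **Calibration.** The default `p_arrest_per_encounter = 0.02` was set so
  that the expected ground-truth arrest fraction among analyzed cells is
  ≈ 10 %, the regime of interest for cognate-target experiments, as
  measured by the generator's own Monte-Carlo oracle
  (`expected_stable_fraction`).

### What the generator does and does not show

Passing the recovery tests shows the *measurement pipeline* is faithful:
planted dead and drifting cells are removed exactly per the thresholds,
ground-truth arrests are called stable, dropout is absorbed by the gap
tolerance, and the pipeline's stable percentage agrees with the
generator's own Monte-Carlo expectation. It does not show that the
generator reproduces real movies. Known gaps: rigid T-cell footprints (no
shape dynamics or polarisation), no segmentation noise beyond frame
dropout, no cell–cell exclusion between T cells, and a chance
end-of-acquisition overlap rate (~18 % of migrating cells happen to sit on
an activating target near the movie end at `p_arrest = 0`) well above the
few-percent baseline real non-cognate controls show — densely tiled
convex targets make grazing overlaps of ≥ 10 % of a small T-cell footprint
easy. Absolute stable percentages from the generator are therefore not
comparable to experimental values; all quantitative acceptance checks are
self-consistency or ground-truth-recovery checks, not comparisons to
experimental percentages.

## Numerical and interface choices

* Coordinates are converted to µm at read time (`pixel_size` scaling for
  TrackMate files in pixel units; TrackMate's calibrated exports use 1.0);
  all thresholds are metric. Frames are 0-based everywhere.
* TrackMate ROI vertices are offsets from the spot position in calibrated
  units (TrackMate convention); spots without an ROI become centroid-only
  observations with a warning; spots in no track are dropped with a logged
  count.
* The canonical CSV dialect writes fixed 9-decimal coordinates in
  track-major, frame-major order, so write→read→write is byte-stable;
  outputs are CSV/JSON rather than spreadsheets for diffability.
* Problem sizes in the shipped checks (field size, cells per field,
  replicate counts in the acceptance script and tests) are chosen so the
  statistical assertions are well-powered while the whole suite stays
  interactive-fast; all are parameters, and larger runs only tighten the
  intervals.

## Known limitations

* Touch detection is polygon-overlap only; sub-frame timing, 3-D contact
  area and synapse ultrastructure are out of scope.
* A stable contact is an end-state call: a cell that arrests in the last
  few frames is indistinguishable from one that grazes a target there.
  The `track_truncated` flag and the configurable gap semantics expose the
  boundary cases; they cannot remove them.
* The density normalisation assumes equal field areas within a group.
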
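# Methods

This note documents the models, conventions and numerical choices behind
slidekit, in the spirit of the methods documentation of the larger
scientific-Python packages: what each procedure assumes, which parameters
matter and why their defaults are what they are, and what the synthetic
tests do and do not demonstrate about real data.

## Coordinate frame and rasterization

All geometry lives in a single world frame in micrometres: origin at the
image's top-left corner, x rightward along columns, y downward along rows.
Pixel (row, col) occupies the half-open square
`[col·s, (col+1)·s) × [row·s, (row+1)·s)` for pixel size `s` (µm/px), with
its center at `((col+0.5)·s, (row+0.5)·s)`. A pixel belongs to a polygon
iff the polygon covers its center point, under a half-open convention
(boundary on the left/top counts) so rasterization is deterministic when
an edge passes exactly through centers. Numerically this is evaluated as
point-in-interior at the center nudged by +1e-6 px in both axes: for
axis-aligned boundaries the nudge reproduces the half-open rule exactly,
and elsewhere it only reclassifies points within 1e-6 px of an edge —
far below any physically meaningful scale. Polygons produced from label
masks have all vertices on pixel corners, so their rasterization is never
boundary-ambiguous.

Invalid polygons (self-intersecting traces from noisy masks) are repaired
by zero-width buffering; if repair yields several parts, the largest is
kept. Holes inside segmented labels are filled: segmented cells are
modelled as simple polygons, and a "hole" inside a thresholded cell is
almost always a staining dropout, not topology.

## Patch grids

Per axis, patch k starts at `k·(w − o)` for patch width `w` and overlap
`o`; the last patch is clamped to the extent boundary, and a single patch
is used when the extent fits in one. Defaults: `w = 200 µm`,
`o = 40 µm` — twice a typical 20 µm cell diameter, following the rule that
the overlap must be at least twice the average cell diameter so that every
cell is complete in at least one patch. Patch rectangles are closed on
their min edges and open on their max edges (last patch closed), so
points in overlap zones are deterministically assigned to every containing
patch while coverage stays exact.

One caveat discovered in testing: the per-point patch multiplicity is
*not* monotone in the overlap (a point lying under two starts at a small
overlap can lie under one start at a larger overlap, because all starts
shift with the step). What does hold, and what the tests assert, is that
coverage is everywhere ≥ 1, the number of patches is non-decreasing in the
overlap, and every point inside an interior overlap band lies in at least
two patches.

## Segmentation contract and the built-in segmenter

A segmenter is a callable `(patch_image, transcripts_subset, params)`
returning either an integer label mask over the patch window or polygons
in world µm. External tools plug in through this contract unchanged. The
built-in segmenter (Gaussian smooth → fixed or Otsu threshold →
4-connected components → minimum-area filter → optional
distance-transform watershed) exists so the full pipeline is testable and
runnable on any machine; it is a real, deterministic segmenter for
high-contrast nuclear stains, not a stand-in for learned models on real
tissue.

Label masks are polygonized along outer pixel edges (union of pixel
squares, collinear vertices dropped), so a hole-free label of n pixels
becomes a polygon of area exactly `n·s²`. This exactness is what lets the
aggregation oracle tests use pixel counts as ground truth.

## Conflict resolution

Candidate conflicts are cross-patch pairs found by a spatial index; each
pair is scored with IOMA = intersection / min(area). Pairs scoring
strictly above 0.5 — the intersection exceeds half of the smaller cell —
are duplicates and are unioned; others are kept. Merges close
transitively through a union-find, which makes the result independent of
patch processing order; the merge test is evaluated once on the original
pairs, not re-evaluated as unions grow (chains are rare and the
transitive closure already joins them). Same-patch pairs are trusted and
never candidates. The 0.07/0.8 cutoffs are QC classifier constants only:
they bin resolved conflicts into clearly-distinct / ambiguous /
clearly-duplicate for the report, and play no role in merging.

## Aggregation

Channel averaging walks the image chunk grid once. Per chunk, cells whose
bounds intersect it are rasterized over their bounding box clipped to the
chunk, and (sum, pixel count) pairs accumulate per cell in float64; means
are taken at the end. Because chunk windows partition the image, a cell
spanning chunks accumulates each pixel exactly once, and the result equals
whole-image rasterization up to float64 summation order (tested to 1e-9
relative over randomized fixtures). Cells covering no pixel center get
mean 0 with a warning.

Transcript counting bins points into square partitions (default 100 µm —
a geometric, hardware-independent stand-in for memory-bounded partitions)
and joins each partition's points against the cells intersecting it. Any
cell covering a point intersects the point's partition, so the result is
exactly the global join for every partition size. A point covered by
several cells (shared borders) goes to the smallest cell id — an
arbitrary but deterministic tie rule; boundary points are counted
(inclusive `covers` predicate).

## Annotation

`X'_j = arcsinh(X_j / (5·Q(0.2, X_j)))` per channel, with the quantile
computed by linear interpolation between order statistics (the most common
convention, pinned for reproducibility). If the 20th percentile is 0
(possible for background-only channels), the divisor falls back to 5× the
smallest positive value; an all-zero column stays zero. The transform is
strictly monotone per channel and exactly invariant to positive channel
rescaling, so annotation is gain-independent. Cells take the population of
the argmax marker channel, ties to the lowest channel index, all-zero
marker rows labelled "unassigned". `refine_by_clusters` relabels any
provided clustering to its majority label (ties lexicographic); it covers
cluster-based refinement generically without depending on a specific
clustering or reference-mapping tool.

## Spatial graph and hop distances

Cell centroids are Delaunay-triangulated; edges longer than 40 µm are
pruned as non-physical contacts, and triangles containing a pruned edge
are dropped (the retained triangles drive niche polygonization).
Degenerate inputs (< 3 points, collinear points) fall back to connecting
all pairs within range; duplicate centroids are jittered by 1e-9 µm with
a fixed seed.

`D(g, g')` is the mean over cells of category g of the hop distance (edge
count, not Euclidean length) to the nearest cell of category g',
computed with one multi-source BFS per g'. Cells with no finite path are
excluded from the mean and reported separately — keeping means finite and
interpretable rather than propagating infinities. The matrix is
asymmetric by construction. The combined network symmetrizes the two
directed entries of each label pair by their mean and weights edges as
`1/max(D̄, ε)` with `ε = 0.5` hops, since the inverse is undefined at
distance 0 (a category fully inside its niche); undefined distances give
no edge. Symmetrization is an interpretation choice — the directed
matrices remain available.

## Niche polygonization

Cross-niche edges are cut; each remaining connected component is one
occurrence of a niche. Border edges are the edges incident to exactly one
retained triangle of the component — the standard boundary operator on a
triangulated region, guaranteeing closed rings — and are linked into
rings; at the rare non-manifold junction (> 2 border edges at a vertex)
the walk takes the leftmost continuation (smallest clockwise turn),
deterministically splitting the junction. The largest ring is the
exterior; a further ring becomes a hole only if the exterior covers it,
otherwise it is a separate lobe of the same pinched component and is
unioned in (this distinction is what preserves the identity polygon area
= Σ retained triangle areas, which the tests check to 1e-6 relative).
Components with fewer than 3 cells carry no triangle and are skipped with
a warning.

Statistics are hole-aware: A = exterior − holes, L = exterior + hole
perimeters, R = 4πA/L². Occurrences below 5% of the niche's largest
component are dropped as clustering artefacts before computing occurrence
counts, means and density; density (total retained cells / total retained
area) is computed after the filter, consistent with reporting on the
retained geometry.

## Visualizer bundle

Open Zarr re-implementation of the pyramidal viewer scheme, not a
byte-compatible proprietary writer. Image levels halve (ceiling) until
both dimensions fit one 1024×1024 tile; each tile is computed only from
the source blocks it overlaps. Downsampling is a 2×2 mean with partial
blocks at odd edges. Transcript levels start at 250 µm tiles and double,
keeping every 4th point of the previous level (stride 4, offset 0, stable
input order — a deterministic reading of "one-fourth retained"); the last
level is the first whose single tile covers the extent. Boundaries are
simplified with tolerance 0.1 µm doubling up to 20 attempts until ≤ 13
vertices, then padded by repeating the last vertex; tables use gene-major
data/cell-index/gene-pointer compression and label-grouped category
indices. Level-0 image, level-0 transcripts and all tables round-trip
losslessly; re-export of unchanged inputs is byte-identical.

## Synthetic tissue generator

The generator emulates a stained tissue tile: cells are regular 24-gons
(closed-form area/perimeter for oracles) with rejection-sampled centers at
pairwise spacing ≥ 2 radii (touching allowed, overlap impossible), a
nuclear channel bright in every cell plus one marker channel per type,
per-cell transcript counts Poisson(λ) placed uniformly inside the
boundary, uniform background transcripts, and niche labels assigned by a
known spatial partition (halves or concentric rings) so graph statistics
have ground truth. One global seed fans out to per-component substreams,
making every stage individually reproducible and the whole output
byte-identical per seed.

Defaults are the package's study conditions: 120 cells of 5 µm radius on
a 200 µm tile at 0.5 µm/px, four channels (DAPI + CD3/CD20/PanCK at 200
vs 5 background intensity, Gaussian noise σ = 3), λ = 50 transcripts per
cell over a 4-gene vocabulary, background 0.001 transcripts/µm². These
sizes keep a full end-to-end run in seconds while leaving every
interacting regime populated (cells split across patch borders, transcripts
in overlap zones, both niches adjacent).

What the generator does **not** emulate: optics (PSF blur,
autofluorescence, channel bleed-through), irregular cell morphology,
density gradients, segmentation-quality degradation at low contrast, or
transcript spatial structure within cells. Passing the recovery tests
therefore shows the pipeline machinery (patching, merging, aggregation,
annotation, statistics) is correct, not that any particular segmenter is
accurate on real tissue.

## Problem sizes in tests and acceptance

The test suite runs on tiles of 80–200 µm with 10–120 cells; the oracle
equivalences use 20 random image fixtures (96×96 px, 15 cells), 500-point
joins at three partition sizes, 50 random graphs of up to 500 nodes, and
5 random niche maps of 80 cells. These sizes were chosen to exercise all
code paths (multi-chunk cells, multi-patch cells, unreachable graph
components, pinched niche components) while keeping the full suite fast
enough to run habitually.

## Known limitations

- Aligned secondary images are handled by transforming coordinates only;
  no resampling of the secondary raster is performed.
- The conflict merge decision is made once per original pair; a union
  that grows past the threshold against a third cell is not re-tested.
- Category labels shared between the two label sets (a cell type named
  like a niche) would collide as nodes of the combined network.
- The bundle is an open re-implementation of the viewer file scheme;
  byte-compatibility with proprietary viewer formats is out of scope, as
  are vendor raw-data readers and the external segmentation/annotation
  tools themselves (they plug in through the documented contracts).
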
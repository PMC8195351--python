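# Methods

This note documents the models, numerical choices and limitations behind
`shapecomp`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Canonical contours

A shape is an ordered closed polygon; the closing edge is implicit (the
first vertex is never duplicated). The canonical form used by every
downstream computation is produced in three steps:

1. **Arc-length-uniform resampling** to N points (default 384). Uniform
   spacing makes index-based operations (smoothing, FFTs, per-point
   histograms) approximate their arc-length counterparts. Resampling is
   linear interpolation along the polyline, so re-canonicalizing an
   already canonical contour moves points only by the chord-vs-arc
   discretization error (empirically < 2e-3 at N = 384).
2. **Normalization**: per-axis minima are shifted to zero, then *both*
   axes are divided by the single joint maximum. A per-axis division
   would destroy the aspect ratio that descriptors such as eccentricity
   and elongation measure, so the joint convention is used; the longer
   bounding-box side maps exactly onto [0, 1].
3. **Orientation and start point**: traversal is forced counter-clockwise
   (signed quantities such as curvature are defined in that frame), and
   the point order is rotated so the leftmost vertex comes first. Ties
   among equally leftmost vertices (within 1e-12) are broken by a seeded
   uniform draw — a fixed convention, reproducible under a fixed seed,
   that avoids making start choice depend on which other shape a contour
   is compared against. Library default seed is 0.

Rasterization fills the polygon on a grid×grid raster of the unit square
(default 256) with a pixel-center inclusion rule. Self-intersecting
outlines are not rejected — they are filled even-odd and flagged on the
mask, since downstream metrics (IoU, skeletons) remain well-defined.

## Descriptor bank

The default bank registers 50 descriptors across seven families. Exact
membership is a configuration, not a fixed law — the registry is a
plug-in table (`DescriptorDefinition`) and every built space records the
bank's content hash so serialized spaces cannot be silently queried with
a different bank.

* **basic**: area, perimeter, solidity, compactness (4πA/P²), convexity,
  eccentricity, major-axis orientation (degrees, (−90, 90]), aspect
  ratio, rectangularity, circular variance of the radial signature,
  centroid offset. Second-order moments are computed analytically on the
  filled polygon (Green's theorem), not on the boundary point cloud, so
  they do not depend on vertex density.
* **curvature**: signed curvature from finite differences of the
  coordinate sequence after periodic Gaussian smoothing with σ = 2
  contour points (the same blur the synthetic generator applies, and
  small enough to leave a 384-point circle's curvature within 2% of 1/r).
  Scalars: mean |κ|, std, total absolute turning ∮|κ|ds, extrema count,
  bending energy ∮κ²ds.
* **fourier**: amplitudes of harmonics of the centroid-distance signature
  r(t), each divided by the DC amplitude (scale invariant, phase
  discarded hence start-point independent). Harmonics 1–8 as scalars, a
  20-harmonic vector, low-frequency energy, spectral entropy.
* **signature**: statistics of r(t) (CV, min/max, zero crossings,
  skewness) and a start-dependent 64-sample normalized signature vector.
* **shape context**: per-point log-polar histograms of relative point
  positions (5 radial × 12 angular bins; radii normalized by the mean
  pairwise distance; innermost radial edge 0 and outermost ∞ so each
  histogram sums to N−1). The bank exposes the mean histogram
  (start-independent), the start-point histogram (start-dependent), the
  chord-length histogram (16 bins on [0, 3] of chords normalized by the
  mean chord; mass-normalized), and raw chord mean/std. Angles are
  absolute, not tangent-relative, so per-point histograms rotate with the
  shape while the chord summaries do not.
* **skeleton**: the mask is thinned to a 1-px skeleton, converted to a
  pixel adjacency graph, and leaf branches shorter than 3% of the mask
  diagonal are pruned (raw thinning sprouts a spur at almost every
  boundary bump). Endpoint/junction/branch counts, skeleton length over
  boundary length, and a rib count (leaf branches off junctions). These
  are integer-valued and raster-dependent — the noisiest family by
  construction.
* **moments**: the seven Hu invariants of the rasterized mask,
  log-compressed (sign × log10|h|) because they span many orders of
  magnitude.

**Distances for vector-valued descriptors** are the Euclidean norm of the
value difference. χ² would be the classical choice for shape-context
histograms, but Euclidean keeps every descriptor's distance a metric on a
common footing and makes the combined distance exactly the Euclidean
distance between per-descriptor difference profiles (which is what the
metric test relies on).

**Start dependence** is declared per definition. Only descriptors
computed from an ordered traversal (the signature vector, the start-point
shape-context histogram) carry the flag; a test asserts the flags are
real (flagged descriptors change under a cyclic shift, unflagged ones do
not).

## Transformations and sensitivity

Rotation (about the area centroid), shear ((x, y) → (x, ax + y) about the
centroid, unit determinant), bloat (centroid radius r → r^0.75, angle
fixed, result renormalized to [0, 1], iterated 1–4 times), and Gaussian
vertex noise with σ expressed as a fraction of the maximum chord length.
Bloat radii are measured in the normalized frame without prescaling: with
coordinates in [0, 1] the typical radius is below 1, so the power map
pushes points outward and inflates concavities, which is the intended
effect. Rotation and shear are applied about the centroid uniformly for
consistency even though only rotation strictly requires it.

Default sweeps: rotation every 15° excluding identity (23 variants),
shear a ∈ {0.2, 0.4, 0.6, 0.8, 1.0}, bloat 1–4 iterations, noise at 8
log-spaced fractions from 0.5% to 4% of the max chord (the count
interpolates the stated endpoints; only the endpoints are prescribed).

Sensitivity of descriptor j to transform T for category exemplar i: take
the absolute descriptor change |s_o − s_t| for every variant t, pool the
changes across the variants of *all* transforms to get d_min and d_max
for that (i, j), min-max normalize, and average over T's variants; the
score S_Tj is the NaN-aware mean over categories. Pooling across
transforms is what makes 0 mean "invariant relative to what other
transforms do to this descriptor"; a descriptor invariant under every
transform yields 0/0 → NaN and drops out of the mean. At least two
transforms are therefore required. Variants are re-canonicalized in start
point (cyclic shift only — no renormalization, which would reintroduce
scale changes the transforms did not make) before descriptor evaluation.

## Shape space

Per-descriptor distance matrices are normalized by their largest corpus
entry; descriptors with zero corpus variation are excluded with a warning
(they would contribute 0/0). The combined distance is the root sum of
squared normalized distances, computed descriptor-by-descriptor so only
one n×n matrix is alive at a time (no n²×K tensor for large corpora).

Classical MDS double-centers the *squared* distance matrix
(B = −½ J D∘D J), the textbook Torgerson construction. Because max
normalization does not guarantee a Euclidean D, negative eigenvalues can
occur; they are excluded from coordinates and from the variance
denominator (variance explained is relative to the positive spectrum).
Eigenvalue ties are broken by stable index order and each retained
eigenvector's largest-magnitude entry is made positive, so serialized
spaces are bit-reproducible and corpus-order-invariant up to that fixed
convention. K defaults to 22 but is auto-reduced (with a warning) for
corpora smaller than K + 1.

Descriptor clustering represents each descriptor by its normalized
pairwise-distance profile over the corpus and clusters the absolute
Pearson correlations of those profiles with affinity propagation
(preference = median similarity, damping 0.5 with one retry at 0.9).
Profile correlation, unlike raw value correlation, is well-defined for
vector-valued descriptors too.

## Embedding novel shapes

A seeded uniform reference subset (default 500, auto-reduced to the
corpus size) is drawn; the (n_ref + 1)² combined distance matrix —
including the new shape, normalized by the *stored* corpus maxima —
is decomposed with classical MDS; the similarity transform (translation,
rotation/reflection, uniform scale) that best maps the references' local
coordinates onto their stored coordinates is applied to the new shape's
row. Reflection is permitted because MDS axes have arbitrary sign; the
reported residual is the RMS over reference shapes of the per-shape
mapping error norm, giving callers a direct quality scale (held-in shapes
are recovered to within a small multiple of it). A novel shape whose raw
descriptor distance exceeds a stored maximum simply produces a normalized
distance above 1 — allowed, since novel shapes may fall outside the
corpus range.

IoU is computed on masks rasterized in the shared normalized frame with
no re-registration: both silhouettes are compared as placed. "Jaccard
index" is ambiguous between the similarity and the dissimilarity reading,
so `iou()` returns both IoU and 1 − IoU under unambiguous names.

## Synthetic corpus

The generator emulates the qualitative variation of natural silhouette
databases with a star-shaped radial profile: an elliptical body
(elongation 1–2.2 across corpus prototypes), 2–6 von-Mises lobes of
relative height 0.15–0.45 (limb-like protrusions, concentration 18 ≈ 30°
half-width), band-limited radial noise of relative amplitude 0.01–0.08
(spikiness), smoothed along the contour with σ = 2 points. Corpus members
jitter their category prototype's continuous parameters multiplicatively
(default 10%) and realize fresh spike noise; lobe positions stay fixed
within a category so members share a body plan. Star-shapedness makes
outlines simple by construction; simplicity is verified anyway with a
bounded retry (25 attempts with perturbed seeds).

What a green test on this corpus does **not** establish: the generator
produces no occlusions, no holes, no multi-part shapes, no sharp corners,
no non-star-shaped geometry (e.g. curled tails), and its category
structure is far cleaner than real taxonomies. Robustness results
(cross-space correlations, category recovery) demonstrate internal
consistency of the pipeline on smooth naturalistic blobs, not performance
on any real silhouette database, and variance-explained figures depend
strongly on corpus diversity.

## Numerical conventions and degenerate inputs

* Consecutive duplicate vertices are dropped at construction; fewer than
  3 distinct points is an error.
* Zero-area (collinear) contours normalize fine but fail moment-based
  descriptors with a degenerate-shape error, recorded per descriptor id
  rather than aborting the whole vector.
* `resample_uniform` is exact on vertices only when targets land on
  vertices; perimeter is preserved within 0.5% for N ≥ 64 on smooth
  shapes (spiky shapes lose perimeter at coarse N — tested explicitly).
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; no global RNG state is touched.

## Known limitations

* Skeleton descriptors are integer-valued and sensitive to rasterization;
  at grid 256 they are stable under right-angle rotation (tested) but not
  under arbitrary rotation.
* The chord and shape-context histograms use fixed bin edges; a value
  sitting exactly on an edge can jump bins under floating-point-level
  perturbations (never observed on generated corpora, but conceivable on
  hand-crafted exact geometry).
* Classical MDS is O(n³) in corpus size; spaces beyond ~5,000 shapes need
  subsampled construction plus embedding, which is the supported path.
* The sensitivity score depends on which transforms are pooled; it is a
  relative, not absolute, measure by design.
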
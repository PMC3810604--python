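# Methods

This note records the statistical definitions, numerical conventions and
design choices behind `scenestats`, in the spirit of a model
documentation page: what is computed, under which assumptions, and what
the synthetic data do and do not establish.

## Annotation model and geometry

A scene is an image of known width × height carrying a list of labeled
polygons (vertex rings in continuous, 0-based pixel coordinates, x
rightward and y downward).  Areas use the absolute shoelace formula and
are therefore orientation-independent; for self-intersecting rings
(which can arise when annotators interpolate occluded boundaries) the
absolute algebraic area only approximates the even-odd rasterized area,
and we accept the polygons as given.  Object "centers" are bounding-box
midpoints ((x_min+x_max)/2, (y_min+y_max)/2) — a deliberate reading of
the loose convention in the field's reports, and the only one consistent
with objects being equally likely on the left and right halves of a
frame.  Pixel-coverage statistics test pixel centers (i+0.5, j+0.5)
against the polygon union with the even-odd rule on the native grid;
pixel centers never have integer coordinates, so edge-degenerate
membership cannot occur.

Label cleaning is data, not code: a user-supplied table maps raw labels
to `rename` or `delete` actions, each tagged with a change class
(misspelling, plural, subordinate, superordinate, synonym, container,
part, other).  Rename targets must be canonical — a target that is
itself a raw key is rejected — which makes a single application
idempotent.

## Ensemble statistics

Six per-scene summaries over "unnamed things":

* density (instance count) and distinct-label count;
* mean and variance of object area as fractions of image area.  The
  variance is the population variance (a one-object scene has variance
  exactly 0).  Because 2-D labeling of a 3-D scene overlaps polygons,
  fractions may sum past 1; we deliberately do not de-overlap, matching
  the per-object size convention.
* area-weighted center of mass of bbox centers, normalized per axis.
  The vertical coordinate is reported as the fraction from the image
  *bottom*, so "higher center of mass" is a larger number (outdoor
  scenes, dominated by sky and far surfaces, score high).
* spacing regularity: the coefficient of variation (sample SD over
  mean) of pairwise bbox-center distances on coordinates normalized by
  image width and height, making the statistic scale-free across image
  sizes.  With exactly two objects the single distance has SD defined
  as 0; with fewer than two the statistic is undefined (NaN, encoded as
  0 when used as a classifier feature).

Superordinate contrasts are pooled-variance two-sample t-tests on
*basic-level category means* — the category, not the scene, is the unit
of analysis, so the 16-category taxonomy yields df = 14 for indoor vs.
outdoor (8 + 8 − 2) and df = 6 for urban vs. natural (4 + 4 − 2).  The
equal-variance form is used because those are the degrees of freedom
that analysis convention implies.

## Bag-of-words statistics

All identity statistics derive from the scenes × vocabulary count
matrix and its presence (count > 0) view.

* **Frequency** is scene-level presence per category; overall tables
  carry both scene counts and instance counts.  Entropy uses instance
  frequencies, H = −Σ p(o) log₂ p(o) with p(o) the instance share —
  the standard Shannon form in bits (this reproduces the log₂ V uniform
  limit, e.g. 9.27 bits for a 617-label vocabulary).
* **Diagnosticity** p(S | O) is the ratio of presence scene counts; each
  object's row over categories sums to 1.  Reports filter objects with
  fewer than 10 scenes of support (rare objects are trivially
  diagnostic); the unfiltered table remains available and is what the
  landmark-object analyses (largest object, most-central object) use.
  Ranking ties break lexicographically.
* **Mutual information** treats presence O and membership S as binary
  variables and computes the plug-in I(S; O) in bits from the 2 × 2
  scene table; the per-object "overall informativeness" is I(O; C)
  against the full K-way category variable (the alternative — summing
  binary MI over categories — is also exposed, the multiway form is
  the default ranking).  0·log 0 ≡ 0 throughout.
* **Co-occurrence probability** of a pair is joint-presence scenes over
  scenes containing *either* object (Jaccard); 1 therefore means the
  two labels are never seen apart.  This normalization is a declared
  package convention, since field usage is not standardized.
* **Frequent n-object groups** use exact support counting: each scene's
  distinct-label set is pruned by singleton support (anti-monotonicity
  guarantees exactness) and its n-subsets enumerated.  This is
  practical because annotated scenes have at most a few tens of
  distinct labels; no approximate mining is involved.

## Structural statistics

Cross-image maps live on a common normalized grid, 64 × 64 by default:
instance polygons are scaled from native image coordinates onto the
grid and rasterized at cell centers.  A coarse common grid makes
differently sized images commensurable and keeps the Bonferroni
correction of the location contrast meaningful (0.05 / 4096 per cell)
rather than vacuous at per-pixel resolution.

The indoor/outdoor location contrast uses the *scene* as the unit: each
scene containing the object contributes its union occupancy mask, and
each cell gets a two-sample t-test between groups.  Cells empty in both
groups produce 0/0 statistics and are assigned p = 1.  A permutation
helper re-labels scenes at random and reports the family-wise rate of
any-significant outcomes; with 200 permutations the empirical rate is
compared against 0.10 (the nominal 0.05 plus two-sigma binomial slack at
n = 200 — a bound fixed in advance of measurement).

Quadrant features assign each instance to the quadrant containing its
bbox center; centers exactly on a midline go to the lower-index quadrant
(left column, top row), a tie-break that preserves the row-sum
conservation quadrant counts = instance counts.

## Classification protocol

"Linear classifier" means libsvm's C-SVC with a linear kernel and the
default C = 1, one-vs-one multiclass voting — deterministic given input
order.  Features are z-scored with the training fold's mean and SD in
every leave-one-out fold (the ensemble features mix counts, fractions
and coordinates, so unstandardized margins would be dominated by
density).  A fold whose training set degenerates to one class predicts
that class.  AUC is macro-averaged one-vs-rest on raw decision values;
A′ uses the standard nonparametric approximation from one-vs-rest hit
and false-alarm rates read off the confusion matrix; binomial tests
against chance are exact upper-tail probabilities.  Chance is 1/16 =
6.25% for basic-level and 1/3 ≈ 33% for superordinate tasks.

Cross-database transfer fits once on one database and predicts every
scene of the other, with bag-of-words features aligned on the union
vocabulary.  Confusion-pattern correlations first normalize rows to
proportions (aggregating through the taxonomy for superordinate-level
comparisons) and correlate off-diagonal cells only, so shared diagonal
strength cannot inflate the similarity of error patterns.

## Synthetic databases

The generator emulates the statistical structure of fully annotated
scene databases; its defaults are the study conditions, not free dials.

* **Taxonomy** — 16 basic-level categories: 8 indoor (bathroom, bedroom,
  conference room, corridor, dining room, kitchen, living room, office),
  4 urban (skyscraper, city center, street, highway), 4 natural (coast,
  open country, mountain, forest).
* **Density** — per-scene object totals are negative binomial with the
  published per-category means (kitchen 33.1 down to mountain 5.1) and
  dispersion k = 4, reflecting strongly overdispersed empirical counts
  (range ~1–88 against a median of ~11).
* **Vocabulary and presence** — each category owns a ranked label list
  (characteristic labels first, then labels shared within the
  superordinate, then a unique tail; list length 3.5× the category's
  expected distinct-label count) with occurrence probabilities following
  a capped power law whose exponent is solved so the probabilities sum
  to the published mean distinct-label count.  Each label is present
  independently with its occurrence probability — so realized presence
  frequencies estimate the profile probabilities directly — and surplus
  instances (total minus distinct) are allocated multinomially with
  weight p⁴, mimicking the empirical pattern that frequent objects also
  recur within a scene.  This combination gives the pooled database a
  Zipf-like rank-frequency curve (log–log slope ≈ −0.87 over the top 50
  ranks at the default sizes).
* **Geometry** — objects are axis-aligned rectangles: downstream
  statistics consume only label, area and bounding box, so rectangles
  exercise every code path while keeping exact-geometry oracles.
  Areas are log-normal, moment-matched to the published per-category
  mean and SD of object size (a stand-in: those moments describe
  per-scene means, and we reuse them per object).  Vertical bbox-center
  placement is a clipped normal band — indoor centers at 0.53 of image
  height from the top, outdoor at 0.35 — reproducing the lower indoor
  center of mass; horizontal placement is uniform.  All rectangles lie
  inside the image.
* **Seeding** — every scene is drawn from an independent substream keyed
  by (seed, category index, scene index), so any single scene is
  reproducible without generating the rest.

A `recovery_profiles()` variant adds, per category, three
category-exclusive labels at occurrence probability 0.9 over a
background vocabulary shared by all categories.  On that database the
exclusive labels must attain diagnosticity 1.0 and top the
mutual-information rankings, a bag-of-words classifier must recover the
category almost perfectly, and the ensemble classifier must beat chance
purely on density/size/placement differences — the parameter-recovery
checks in the test suite.

What the synthetic data do **not** emulate: photographic pixel content,
object co-occurrence dependence beyond shared vocabularies, non-convex
or overlapping-in-depth polygon shapes, annotator noise (typos enter
only through user-supplied cleaning tables), and database-specific
photographer biases.  Passing tests therefore establish the correctness
and calibration of the *machinery* on data with the assumed structure —
not empirical claims about any real scene corpus.

## Problem sizes and runtime choices

Test and acceptance runs use 16 × 50 scenes for classification checks,
16 × 20–30 scenes for marginal-statistics checks, and 1000
scenes/category (two categories) for occurrence-probability recovery —
sizes at which the Monte-Carlo tolerances used (±0.05 on presence
frequencies, ±0.3 on the Zipf slope, the 0.10 family-wise bound) are
comfortably calibrated.  Leave-one-out evaluation refits the classifier
for every scene; at these sizes a full suite completes in about a
minute on one CPU.

## Known limitations

* The even-odd pixel-center coverage convention can differ from
  anti-aliased or winding-rule rasterizers by a boundary-pixel fringe.
* Plug-in entropy and MI estimates are biased upward for sparse tables;
  no small-sample correction is applied (rankings, the primary use, are
  insensitive to the shared bias).
* The location-contrast t-test treats per-scene binary occupancy as
  approximately normal; the permutation calibration exists precisely to
  check the family-wise behavior of that approximation.
* `cross_database` assumes compatible label conventions; it does not
  attempt synonym resolution across databases.
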
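# scenestats

Object–scene context statistics for polygon-annotated scene databases.

Human observers recognize a kitchen or a coastline in a glance, and the
objects a scene contains are a large part of why: objects are not strewn
randomly through the world but follow regularities of identity, number,
size and position.  `scenestats` quantifies these regularities in fully
labeled scene databases (the LabelMe annotation style: every region in
every image outlined with a polygon and given a basic-level name) and
measures how much each kind of regularity contributes to scene
categorization.  It is aimed at visual-cognition researchers who need
ground-truth object statistics to design experiments (which objects are
*frequent* in a category vs. merely *plausible*?), and at computer-vision
practitioners choosing informative object detectors.

## The three levels of description

For a database of scenes in basic-level categories (e.g. 16 categories
grouped into *indoor*, *urban* and *natural* superordinates), the package
computes:

**Ensemble statistics** — six per-scene summaries that treat annotations
as unnamed "things": object density *N*, distinct-label count, mean and
variance of object area (as fractions of image area), the area-weighted
center of mass (x̄, ȳ) of bounding-box centers, and spacing regularity
CV = σ(d)/d̄ over pairwise center distances.

**Bag of words** — statistics of object identity with layout ignored.
Object frequency per category and the Zipf rank–frequency law; the
*diagnosticity* of an object for a category, p(S | O) estimated as
(scenes of S containing O)/(scenes containing O); scene–object
specificity; co-occurrence and frequent n-object groups (apriori-style
exact support counting); unique object combinations; the label entropy
H = −Σ p(o) log₂ p(o); and the mutual information between binary object
presence and category membership,
I(S; O) = H(S) − H(S | O), in bits, plus each object's information about
the full K-way category variable.

**Structural statistics** — where objects sit in the image plane:
per-object position variance var(x/w) + var(y/h), occupancy maps on a
common normalized grid, indoor/outdoor location-contrast maps with
Bonferroni-corrected per-cell t-tests, and quadrant features (each
object counted in the image quadrant holding its bbox center).

Each representation's sufficiency for categorization is evaluated with a
linear maximum-margin classifier (libsvm linear kernel, C = 1,
one-vs-one voting) under leave-one-out cross-validation, with exact
binomial tests against chance (6.25% for 16-way, 33% for 3-way),
macro one-vs-rest AUC, and the nonparametric sensitivity index
A′ = ½ + (H−F)(1+H−F)/(4H(1−F)) for comparing classifiers to human hit /
false-alarm rates.

Because real annotated databases are rarely redistributable, the package
includes a seeded synthetic-annotation generator (`scenestats.synthetic`)
that reproduces the statistical structure these analyses assume —
category-specific vocabularies with Zipfian marginals, overdispersed
object counts, log-normal sizes, superordinate-dependent vertical
placement — so the entire pipeline runs end-to-end with no download.

## Worked example

```python
from scenestats import (GeneratorConfig, default_profiles, generate_database,
                        superordinate_contrast, ensemble_feature_matrix,
                        loo_evaluate, bow)

config = GeneratorConfig(profiles=tuple(default_profiles()),
                         scenes_per_category=20, seed=0)
db = generate_database(config)
print(f"{len(db.scenes)} scenes, {len(db.vocabulary)} distinct labels")

entropy, limit = bow.database_entropy(db)
print(f"label entropy: {entropy:.2f} bits/object (uniform limit {limit:.2f})")

t, df, p = superordinate_contrast(db, "density", "indoor_vs_outdoor")
print(f"indoor vs outdoor object density: t({df}) = {t:.2f}, p = {p:.1e}")

diag = bow.diagnosticity(db, min_instances=10)
print("most diagnostic kitchen objects:",
      ", ".join(f"{o} ({v:.2f})" for o, v in diag.top_for("kitchen", 3).items()))

X, labels = ensemble_feature_matrix(db)
rep = loo_evaluate(X, labels)
print(f"ensemble LOO accuracy: {100*rep.accuracy:.1f}% "
      f"(chance {100*rep.chance:.2f}%, AUC {rep.auc:.2f})")
```

Output:

```
320 scenes, 315 distinct labels
label entropy: 6.58 bits/object (uniform limit 8.30)
indoor vs outdoor object density: t(14) = 3.75, p = 2.1e-03
most diagnostic kitchen objects: cabinet (1.00), counter (1.00), kitchen_obj02 (1.00)
ensemble LOO accuracy: 40.0% (chance 6.25%, AUC 0.90)
```

Reading the numbers: indoor categories carry significantly more labeled
objects than outdoor ones (the t-test compares the 8 indoor against the
8 outdoor *category means*, hence 14 degrees of freedom); `cabinet` and
`counter` are fully diagnostic — a scene containing them is always a
kitchen; and the six ensemble statistics alone, which never look at an
object's name, already support 16-way categorization far above the 6.25%
chance level.

## Command line

```bash
scenestats simulate --out demo --scenes-per-category 20 --seed 0
scenestats run --input-dir demo/annotations --taxonomy demo/taxonomy.csv \
    --out demo/report
```

`run` writes per-scene and per-category CSV tables, diagnosticity and
mutual-information tables, structural maps, classification reports, and
a `manifest.json` recording the seed, package version and input digests
so every table is regenerable from the manifest alone.  Label cleaning
(typos, plurals, subordinate terms, synonyms) is table-driven: pass a
3-column CSV (`raw,action,change_class`, action `rename:<target>` or
`delete`) via `--normalization`.

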
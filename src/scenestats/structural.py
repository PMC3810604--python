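"""Structural statistics: where labeled objects sit in the image plane.

All cross-image maps live on a common normalized grid (64 x 64 by
default): each instance's polygon is rasterized at the grid's cell
centers after scaling the native image coordinates onto the grid, so
images of different sizes are directly comparable.  A coarse grid also
keeps the Bonferroni correction of the per-cell location contrasts
meaningful.

Provided statistics:

* per-object variance of normalized center position (how stereotyped an
  object's location is);
* occupancy maps (summed instance masks — where the object tends to be);
* indoor vs. outdoor location contrast maps with Bonferroni-corrected
  per-cell two-sample t-tests over per-scene occupancy, plus a
  permutation-calibration helper;
* pooled occupancy of each category's most diagnostic / most informative
  / random object;
* quadrant features (objects x {TL, TR, BL, BR} counts by bbox center),
  a coarse spatial extension of the bag-of-words representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from scenestats.annotation_io import (
    SceneAnnotation,
    SceneDatabase,
    object_bbox_center,
    rasterize_mask,
)
from scenestats import bow

__all__ = [
    "position_variance",
    "position_variance_table",
    "OccupancyMap",
    "occupancy_map",
    "ContrastMap",
    "location_contrast_map",
    "location_contrast_permutation",
    "PooledMap",
    "informative_object_map",
    "QUADRANTS",
    "quadrant_features",
    "quadrant_matrix",
]

QUADRANTS = ("TL", "TR", "BL", "BR")


# ---------------------------------------------------------------------------
# Position variance
# ---------------------------------------------------------------------------


def _normalized_centers(
    db: SceneDatabase, obj: str, category: str | None = None
) -> np.ndarray:
    pts = []
    for scene in db.scenes:
        if category is not None and scene.category != category:
            continue
        for o in scene.objects:
            if o.label == obj:
                cx, cy = object_bbox_center(o.polygon)
                pts.append((cx / scene.width, cy / scene.height))
    return np.array(pts) if pts else np.empty((0, 2))


def position_variance(
    db: SceneDatabase, obj: str, category: str | None = None
) -> float:
    """Dispersion of an object's normalized bbox-center positions.

    ``var(x/width) + var(y/height)`` (sample variance) over all instances,
    optionally restricted to one category.  NaN with fewer than 2
    instances.  Low values mark boundary-bound objects whose location is
    nearly fixed across the database.
    """
    pts = _normalized_centers(db, obj, category)
    if len(pts) < 2:
        return float("nan")
    return float(pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))


def position_variance_table(db: SceneDatabase) -> pd.Series:
    """Position variance for every vocabulary object (NaN if <2 instances)."""
    return pd.Series(
        {obj: position_variance(db, obj) for obj in db.vocabulary},
        name="position_variance",
    )


# ---------------------------------------------------------------------------
# Occupancy maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupancyMap:
    """Summed instance masks of one object on the normalized grid."""

    grid: np.ndarray  # (H, W) non-negative counts
    object: str
    n_instances: int


def _instance_masks(
    db: SceneDatabase,
    obj: str,
    grid: int,
    category: str | None = None,
) -> list[np.ndarray]:
    masks = []
    for scene in db.scenes:
        if category is not None and scene.category != category:
            continue
        scale = (grid / scene.width, grid / scene.height)
        for o in scene.objects:
            if o.label == obj:
                masks.append(rasterize_mask(o.polygon, grid, grid, scale=scale))
    return masks


def occupancy_map(
    db: SceneDatabase, obj: str, grid: int = 64, category: str | None = None
) -> OccupancyMap:
    """Sum of rasterized instance masks of ``obj`` on a grid x grid lattice."""
    masks = _instance_masks(db, obj, grid, category)
    total = (
        np.sum(masks, axis=0).astype(int)
        if masks
        else np.zeros((grid, grid), dtype=int)
    )
    return OccupancyMap(grid=total, object=obj, n_instances=len(masks))


# ---------------------------------------------------------------------------
# Location contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastMap:
    """Signed occupancy difference between two scene groups for one object.

    ``diff`` is mean per-scene occupancy in group A minus group B per
    cell; ``p_values`` the per-cell two-sample t-test p-values, tested at
    the Bonferroni-corrected level ``alpha / n_cells``.
    """

    object: str
    diff: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    any_significant: bool
    n_scenes: tuple[int, int]
    alpha: float


def _scene_union_masks(
    db: SceneDatabase, obj: str, grid: int, group: set[str]
) -> tuple[np.ndarray, int]:
    """Per-scene binary occupancy (union over the scene's instances).

    Only scenes containing the object contribute.  Returns the stacked
    (n_scenes, grid*grid) array and the total instance count.
    """
    rows, n_inst = [], 0
    for scene in db.scenes:
        if db.taxonomy[scene.category] not in group:
            continue
        inst = [o for o in scene.objects if o.label == obj]
        if not inst:
            continue
        n_inst += len(inst)
        scale = (grid / scene.width, grid / scene.height)
        union = np.zeros((grid, grid), dtype=bool)
        for o in inst:
            union |= rasterize_mask(o.polygon, grid, grid, scale=scale)
        rows.append(union.ravel().astype(float))
    stacked = np.array(rows) if rows else np.empty((0, grid * grid))
    return stacked, n_inst


def _cellwise_contrast(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_cells = a.shape[1]
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # cells empty in both groups yield 0/0 t statistics; they are
        # mapped to p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0)
    # cells with zero variance in both groups and equal means: no evidence
    p = np.where(np.isnan(p), 1.0, p)
    significant = p < alpha / n_cells
    return diff, p, significant


def location_contrast_map(
    db: SceneDatabase,
    obj: str,
    grid: int = 64,
    alpha: float = 0.05,
    min_instances: int = 10,
) -> ContrastMap:
    """Indoor-vs-outdoor location contrast for one object.

    For each scene containing the object, its instances' union mask on
    the normalized grid is the scene's occupancy pattern.  Cell by cell,
    indoor scenes are compared with outdoor scenes by a two-sample t-test
    at the Bonferroni-corrected level ``alpha / n_cells``; ``diff`` is
    positive where the object occupies the cell more often indoors.
    Antisymmetric under swapping the groups.  Requires at least
    ``min_instances`` instances on each side.
    """
    a, na = _scene_union_masks(db, obj, grid, {"indoor"})
    b, nb = _scene_union_masks(db, obj, grid, {"urban", "natural"})
    if na < min_instances or nb < min_instances:
        raise ValueError(
            f"object {obj!r} needs >= {min_instances} instances per group "
            f"(got indoor {na}, outdoor {nb})"
        )
    diff, p, significant = _cellwise_contrast(a, b, alpha)
    return ContrastMap(
        object=obj,
        diff=diff.reshape(grid, grid),
        p_values=p.reshape(grid, grid),
        significant=significant.reshape(grid, grid),
        any_significant=bool(significant.any()),
        n_scenes=(a.shape[0], b.shape[0]),
        alpha=alpha,
    )


def location_contrast_permutation(
    db: SceneDatabase,
    obj: str,
    grid: int = 64,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """Family-wise false-positive rate of the contrast under permuted groups.

    Scene group labels (indoor/outdoor) are randomly reassigned while the
    occupancy patterns stay fixed; the returned value is the fraction of
    permutations in which any Bonferroni-significant cell appears.  With a
    correct per-cell test this empirical rate stays near (below) alpha.
    """
    a, _ = _scene_union_masks(db, obj, grid, {"indoor"})
    b, _ = _scene_union_masks(db, obj, grid, {"urban", "natural"})
    pooled = np.vstack([a, b])
    na = a.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        _, _, significant = _cellwise_contrast(pa, pb, alpha)
        hits += bool(significant.any())
    return hits / n_permutations


# ---------------------------------------------------------------------------
# Diagnostic / informative object maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledMap:
    """Occupancy pooled over categories, one designated object each."""

    map: OccupancyMap
    chosen: dict[str, str]  # category -> object


def informative_object_map(
    db: SceneDatabase,
    mode: str = "top_mi",
    grid: int = 64,
    seed: int = 0,
) -> PooledMap:
    """Pooled occupancy of each category's designated object.

    ``mode="top_mi"`` picks, per category, the object with the highest
    binary mutual information with that category; ``"top_diagnosticity"``
    the most diagnostic object (support-filtered table when non-empty);
    ``"random"`` a seeded uniform draw from the objects present in the
    category.  Instance masks are restricted to the designating category's
    scenes and summed, so the pooled mass equals the sum of the
    per-category masses.
    """
    if mode not in ("top_mi", "top_diagnosticity", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    if mode == "top_mi":
        mi = bow.mutual_information(db)
        for cat in db.categories:
            if db.scenes_of(cat):
                chosen[cat] = mi.top_for(cat, k=1).index[0]
    elif mode == "top_diagnosticity":
        diag = bow.diagnosticity(db)
        for cat in db.categories:
            if not db.scenes_of(cat):
                continue
            table = diag.filtered()
            if table.empty:
                table = diag.table
            col = table[cat].sort_index().sort_values(
                ascending=False, kind="stable"
            )
            chosen[cat] = col.index[0]
    else:
        for cat in db.categories:
            present = sorted(
                {o.label for s in db.scenes_of(cat) for o in s.objects}
            )
            if present:
                chosen[cat] = present[rng.integers(len(present))]

    total = np.zeros((grid, grid), dtype=int)
    n_inst = 0
    for cat, obj in chosen.items():
        m = occupancy_map(db, obj, grid, category=cat)
        total += m.grid
        n_inst += m.n_instances
    return PooledMap(
        map=OccupancyMap(grid=total, object=f"pooled:{mode}", n_instances=n_inst),
        chosen=chosen,
    )


# ---------------------------------------------------------------------------
# Quadrant features
# ---------------------------------------------------------------------------


def quadrant_features(scene: SceneAnnotation) -> dict[tuple[str, str], int]:
    """Instance counts per (label, quadrant) for one scene.

    The quadrant is the one containing the object's bbox center; centers
    exactly on a midline go to the lower-index quadrant (left column /
    top row), so an object centered on the image center counts as TL.
    Counts over quadrants sum to the scene's instance count.
    """
    counts: dict[tuple[str, str], int] = {}
    mx, my = scene.width / 2.0, scene.height / 2.0
    for o in scene.objects:
        cx, cy = object_bbox_center(o.polygon)
        col = 0 if cx <= mx else 1
        row = 0 if cy <= my else 1
        quad = QUADRANTS[row * 2 + col]
        counts[(o.label, quad)] = counts.get((o.label, quad), 0) + 1
    return counts


def quadrant_matrix(db: SceneDatabase) -> pd.DataFrame:
    """Scenes x (vocabulary x 4 quadrants) count matrix.

    Compared with the bag-of-words count matrix every object is
    represented four times, once per quadrant.  Columns are a
    (label, quadrant) MultiIndex.
    """
    vocab = list(db.vocabulary)
    columns = pd.MultiIndex.from_product(
        [vocab, QUADRANTS], names=["object", "quadrant"]
    )
    col_idx = {pair: i for i, pair in enumerate(columns)}
    data = np.zeros((len(db.scenes), len(columns)), dtype=int)
    for i, scene in enumerate(db.scenes):
        for pair, c in quadrant_features(scene).items():
            data[i, col_idx[pair]] = c
    return pd.DataFrame(
        data, index=[s.scene_id for s in db.scenes], columns=columns
    )
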
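"""Per-scene ensemble statistics and their category-level contrasts.

Ensemble statistics summarize a scene's objects as unnamed "things":
how many there are, how large they are, where their mass sits, and how
regularly they are spaced.  Six statistics are computed per scene:

``density``
    Total number of labeled regions.
``unique_count``
    Number of distinct labels.
``mean_size`` / ``size_variance``
    Mean and variance of object areas expressed as fractions of image
    area.  Areas of overlapping polygons are counted per object (2-D
    labeling of a 3-D scene overlaps, so the fractions can sum past 1).
``com_x`` / ``com_y``
    Area-weighted mean of object bbox centers, normalized per axis to
    [0, 1].  ``com_y`` is measured from the image *bottom*, so a larger
    value means the mass of objects sits higher in the frame.
``spacing_cv``
    Coefficient of variation (sample SD / mean) of pairwise distances
    between bbox centers, on coordinates normalized by image width and
    height — scale-free, so differently sized images are comparable.

Category summaries average these statistics per basic-level category;
superordinate contrasts compare groups of category means with an
equal-variance two-sample t-test (the unit of analysis is the category,
giving 8+8-2 = 14 df for indoor vs. outdoor and 4+4-2 = 6 df for urban
vs. natural on the 16-category taxonomy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from scenestats.annotation_io import (
    SceneAnnotation,
    SceneDatabase,
    object_bbox_center,
    polygon_area,
)

FEATURE_NAMES = (
    "density",
    "unique_count",
    "mean_size",
    "size_variance",
    "com_x",
    "com_y",
    "spacing_cv",
)

#: The six ensemble statistics used as classifier features (the horizontal
#: and vertical center-of-mass coordinates jointly form the "center of
#: mass" statistic, and joint subsets treat them as one feature).
STATISTIC_GROUPS: dict[str, tuple[str, ...]] = {
    "density": ("density",),
    "unique_count": ("unique_count",),
    "mean_size": ("mean_size",),
    "size_variance": ("size_variance",),
    "center_of_mass": ("com_x", "com_y"),
    "spacing_cv": ("spacing_cv",),
}


@dataclass(frozen=True)
class EnsembleFeatures:
    density: int
    unique_count: int
    mean_size: float
    size_variance: float
    com_x: float
    com_y: float
    spacing_cv: float  # NaN when undefined (fewer than 2 objects)

    @property
    def spacing_defined(self) -> bool:
        return not math.isnan(self.spacing_cv)

    def as_array(self, fill_spacing: float = 0.0) -> np.ndarray:
        """Feature vector in :data:`FEATURE_NAMES` order.

        An undefined spacing CV is encoded as ``fill_spacing`` so that
        single-object scenes remain usable as classifier inputs.
        """
        v = np.array(
            [
                self.density,
                self.unique_count,
                self.mean_size,
                self.size_variance,
                self.com_x,
                self.com_y,
                self.spacing_cv,
            ],
            dtype=float,
        )
        if math.isnan(v[-1]):
            v[-1] = fill_spacing
        return v


def ensemble_features(scene: SceneAnnotation) -> EnsembleFeatures:
    """Compute the six ensemble statistics for one scene.

    Raises on a scene with no objects.  With exactly two objects there is
    a single pairwise distance; its sample SD is defined as 0, so the
    spacing CV is 0.  With fewer than two objects the spacing CV is
    undefined and returned as NaN.
    """
    if not scene.objects:
        raise ValueError(f"scene {scene.scene_id!r} has no objects")
    w, h = scene.width, scene.height
    img_area = w * h

    areas = np.array([polygon_area(o.polygon) for o in scene.objects])
    fracs = areas / img_area
    centers = np.array([object_bbox_center(o.polygon) for o in scene.objects])
    norm = centers / np.array([w, h])

    weights = areas if areas.sum() > 0 else np.ones_like(areas)
    com_x = float(np.average(norm[:, 0], weights=weights))
    com_y_top = float(np.average(norm[:, 1], weights=weights))

    n = len(scene.objects)
    if n < 2:
        spacing_cv = float("nan")
    else:
        d = pdist(norm)
        sd = 0.0 if len(d) < 2 else float(np.std(d, ddof=1))
        mean_d = float(d.mean())
        spacing_cv = sd / mean_d if mean_d > 0 else 0.0

    return EnsembleFeatures(
        density=n,
        unique_count=len(set(scene.labels)),
        mean_size=float(fracs.mean()),
        size_variance=float(fracs.var()),  # population variance: 1 object -> 0
        com_x=com_x,
        com_y=1.0 - com_y_top,  # report as fraction from the image bottom
        spacing_cv=spacing_cv,
    )


def feature_frame(db: SceneDatabase) -> pd.DataFrame:
    """Per-scene ensemble features with scene id, category, superordinate."""
    rows = []
    for scene in db.scenes:
        f = ensemble_features(scene)
        rows.append(
            {
                "scene_id": scene.scene_id,
                "category": scene.category,
                "superordinate": db.taxonomy[scene.category],
                **{name: getattr(f, name) for name in FEATURE_NAMES},
            }
        )
    return pd.DataFrame(rows).set_index("scene_id")


def ensemble_feature_matrix(
    db: SceneDatabase, fill_spacing: float = 0.0
) -> tuple[np.ndarray, list[str]]:
    """(scenes x 7) feature matrix and per-scene category labels."""
    X = np.array(
        [ensemble_features(s).as_array(fill_spacing) for s in db.scenes]
    )
    labels = [s.category for s in db.scenes]
    return X, labels


def category_summary(db: SceneDatabase) -> pd.DataFrame:
    """Per-category mean and SD of each ensemble statistic.

    Returns a frame indexed by category with a (statistic, mean/sd) column
    MultiIndex.  Categories without scenes are omitted.  Scene-level NaNs
    (undefined spacing) are ignored within each cell.
    """
    frame = feature_frame(db)
    grouped = frame.groupby("category")[list(FEATURE_NAMES)].agg(
        ["mean", "std"]
    )
    grouped.columns = grouped.columns.set_names(["statistic", "moment"])
    grouped = grouped.rename(columns={"std": "sd"}, level="moment")
    return grouped


_SPLITS = {
    "indoor_vs_outdoor": (("indoor",), ("urban", "natural")),
    "urban_vs_natural": (("urban",), ("natural",)),
}


def superordinate_contrast(
    db: SceneDatabase, statistic: str, split: str = "indoor_vs_outdoor"
) -> tuple[float, int, float]:
    """Two-sample t-test on basic-level category means of one statistic.

    ``split`` is ``"indoor_vs_outdoor"`` or ``"urban_vs_natural"``.  The
    test is pooled-variance (equal-variance) and two-tailed, with the
    category as the unit of analysis.  Returns ``(t, df, p)``.
    """
    if statistic not in FEATURE_NAMES:
        raise ValueError(f"unknown ensemble statistic {statistic!r}")
    if split not in _SPLITS:
        raise ValueError(f"unknown split {split!r}")
    group_a, group_b = _SPLITS[split]

    frame = feature_frame(db)
    cat_means = frame.groupby("category")[statistic].mean()
    sup = {c: db.taxonomy[c] for c in cat_means.index}

    a = cat_means[[c for c in cat_means.index if sup[c] in group_a]].to_numpy()
    b = cat_means[[c for c in cat_means.index if sup[c] in group_b]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each side of the contrast needs >=2 categories")

    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return float(t), int(df), float(p)
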
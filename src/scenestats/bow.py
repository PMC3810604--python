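"""Bag-of-words statistics: object identities without spatial layout.

A scene is reduced to the multiset of its object labels.  From the
scenes x vocabulary count matrix this module derives:

* object frequency (overall and per category) and the Zipf rank-frequency
  relationship;
* *diagnosticity* — p(scene category | object present), the probability
  that a scene belongs to a category given that it contains the object;
* *scene-object specificity* — in how many basic-level categories an
  object is found at all;
* object pair co-occurrence and frequent n-object groups (apriori-style
  support counting), with group diagnosticity;
* the number of unique object combinations observed;
* Shannon entropy of the label distribution, and the mutual information
  between binary object presence and (binary or full multiway) category
  membership.

Entropy uses instance-count probabilities; diagnosticity and mutual
information use scene-level presence.  All rankings break ties
lexicographically so results are deterministic.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scenestats.annotation_io import (
    SceneDatabase,
    object_bbox_center,
    polygon_area,
)

__all__ = [
    "count_matrix",
    "presence_matrix",
    "object_frequency",
    "rank_frequency",
    "DiagnosticityTable",
    "diagnosticity",
    "LandmarkDiagnosticity",
    "landmark_object_diagnosticity",
    "specificity",
    "CooccurrenceResult",
    "cooccurrence",
    "frequent_groups",
    "group_diagnosticity",
    "UniqueCombinations",
    "unique_combinations",
    "combination_count",
    "database_entropy",
    "MITable",
    "mutual_information",
]


# ---------------------------------------------------------------------------
# Count and presence matrices
# ---------------------------------------------------------------------------


def count_matrix(db: SceneDatabase) -> pd.DataFrame:
    """Scenes x vocabulary matrix of instance counts.

    Rows are scene ids (database order), columns the sorted vocabulary.
    """
    vocab = list(db.vocabulary)
    col = {v: i for i, v in enumerate(vocab)}
    data = np.zeros((len(db.scenes), len(vocab)), dtype=int)
    for i, scene in enumerate(db.scenes):
        for label in scene.labels:
            data[i, col[label]] += 1
    return pd.DataFrame(
        data, index=[s.scene_id for s in db.scenes], columns=vocab
    )


def presence_matrix(db: SceneDatabase) -> pd.DataFrame:
    """Boolean presence view of :func:`count_matrix`."""
    return count_matrix(db) > 0


# ---------------------------------------------------------------------------
# Frequency
# ---------------------------------------------------------------------------


def object_frequency(
    db: SceneDatabase,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Object frequencies per category and overall.

    Returns ``(per_category, overall)``:

    * ``per_category`` — objects x categories frame, each cell the
      fraction of that category's scenes containing at least one instance;
    * ``overall`` — per object: ``n_scenes`` (scenes containing it),
      ``scene_fraction``, and ``n_instances`` (total instance count),
      sorted by descending instance count then label.
    """
    counts = count_matrix(db)
    pres = counts > 0
    cats = pd.Series([s.category for s in db.scenes], index=counts.index)

    per_category = pres.groupby(cats).mean().T
    per_category = per_category[sorted(per_category.columns)]

    overall = pd.DataFrame(
        {
            "n_scenes": pres.sum(axis=0),
            "scene_fraction": pres.mean(axis=0),
            "n_instances": counts.sum(axis=0),
        }
    )
    overall = overall.sort_index().sort_values(
        "n_instances", ascending=False, kind="stable"
    )
    return per_category, overall


def rank_frequency(db: SceneDatabase) -> tuple[pd.DataFrame, float]:
    """Descending instance-count table with frequency rank, plus the
    least-squares slope of log10(count) on log10(rank).

    A slope near -1 is the classic Zipf relationship.  Requires at least
    two distinct objects.
    """
    counts = count_matrix(db).sum(axis=0)
    if len(counts) < 2:
        raise ValueError("rank-frequency needs >=2 distinct objects")
    table = counts.rename("count").to_frame()
    table = table.sort_index().sort_values("count", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    slope = zipf_slope(table["count"].to_numpy())
    return table, slope


def zipf_slope(sorted_counts: np.ndarray, top: int | None = None) -> float:
    """Least-squares log-log slope of a descending count sequence."""
    c = np.asarray(sorted_counts, dtype=float)
    if top is not None:
        c = c[:top]
    r = np.arange(1, len(c) + 1, dtype=float)
    x, y = np.log10(r), np.log10(c)
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# Diagnosticity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticityTable:
    """p(category | object present) with per-object scene support.

    ``table`` is objects x categories; each row sums to 1.  ``support``
    counts the scenes containing the object.  Rare objects are trivially
    diagnostic (a one-off object is fully diagnostic of wherever it was
    seen), so reports conventionally filter at ``min_instances``.
    """

    table: pd.DataFrame
    support: pd.Series
    min_instances: int = 10

    def filtered(self, min_instances: int | None = None) -> pd.DataFrame:
        m = self.min_instances if min_instances is None else min_instances
        return self.table.loc[self.support >= m]

    def top_for(self, category: str, k: int = 10, *, filtered: bool = True) -> pd.Series:
        table = self.filtered() if filtered else self.table
        col = table[category]
        return col.sort_index().sort_values(ascending=False, kind="stable").head(k)


def diagnosticity(db: SceneDatabase, min_instances: int = 10) -> DiagnosticityTable:
    """Estimate p(category | object present) for every object.

    The estimate is (# scenes of the category containing the object) /
    (# scenes containing the object).  ``min_instances`` is the default
    reporting filter; the full table remains available.
    """
    pres = presence_matrix(db)
    cats = pd.Series([s.category for s in db.scenes], index=pres.index)
    joint = pres.groupby(cats).sum().T  # objects x categories scene counts
    joint = joint[sorted(joint.columns)]
    support = pres.sum(axis=0)
    table = joint.div(support, axis=0)
    return DiagnosticityTable(table=table, support=support, min_instances=min_instances)


@dataclass(frozen=True)
class LandmarkDiagnosticity:
    """Per-scene diagnosticity of one designated object per scene."""

    values: pd.Series  # indexed by scene id
    mean: float
    ci95: tuple[float, float]
    objects: pd.Series  # the selected object per scene


def landmark_object_diagnosticity(
    db: SceneDatabase, mode: str = "largest"
) -> LandmarkDiagnosticity:
    """Diagnosticity of a scene's landmark object for its own category.

    ``mode="largest"`` selects the object with the greatest polygon area;
    ``mode="most_central"`` the object whose bbox center is nearest the
    image center.  Ties break to the lexicographically smaller label.
    The diagnosticity table is used unfiltered.  Returns the per-scene
    distribution with its mean and 95% percentile interval.
    """
    if mode not in ("largest", "most_central"):
        raise ValueError(f"unknown mode {mode!r}")
    diag = diagnosticity(db).table
    values, chosen = {}, {}
    for scene in db.scenes:
        if not scene.objects:
            continue
        if mode == "largest":
            # maximize area; ties -> smaller label
            key = lambda o: (-polygon_area(o.polygon), o.label)
        else:
            cx, cy = scene.width / 2.0, scene.height / 2.0
            key = lambda o: (
                math.dist(object_bbox_center(o.polygon), (cx, cy)),
                o.label,
            )
        obj = min(scene.objects, key=key)
        chosen[scene.scene_id] = obj.label
        values[scene.scene_id] = float(diag.loc[obj.label, scene.category])
    series = pd.Series(values, name=f"{mode}_diagnosticity")
    lo, hi = np.percentile(series.to_numpy(), [2.5, 97.5])
    return LandmarkDiagnosticity(
        values=series,
        mean=float(series.mean()),
        ci95=(float(lo), float(hi)),
        objects=pd.Series(chosen),
    )


def specificity(db: SceneDatabase) -> pd.Series:
    """Number of basic-level categories in which each object is found."""
    pres = presence_matrix(db)
    cats = pd.Series([s.category for s in db.scenes], index=pres.index)
    return (pres.groupby(cats).any()).sum(axis=0).rename("n_categories")


def specificity_histogram(spec: pd.Series, n_categories: int) -> pd.Series:
    """Histogram of specificity values over 1..n_categories."""
    return spec.value_counts().reindex(
        range(1, n_categories + 1), fill_value=0
    )


# ---------------------------------------------------------------------------
# Pairs and groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CooccurrenceResult:
    """Joint-presence counts and pairwise co-occurrence probabilities.

    ``counts`` is the symmetric objects x objects joint-presence scene
    count (diagonal: scenes containing the object).  ``probability`` is
    joint-presence scenes divided by scenes containing *either* object
    (Jaccard); a probability of 1 means the two objects are always found
    together.  ``sparsity`` is the fraction of possible object pairs ever
    observed together.
    """

    counts: pd.DataFrame
    probability: pd.DataFrame
    sparsity: float
    always_together: tuple[tuple[str, str], ...]


def cooccurrence(db: SceneDatabase) -> CooccurrenceResult:
    pres = presence_matrix(db)
    P = pres.to_numpy(dtype=int)
    joint = P.T @ P
    vocab = list(pres.columns)
    n_obj = np.diag(joint)
    either = n_obj[:, None] + n_obj[None, :] - joint
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(either > 0, joint / np.maximum(either, 1), 0.0)
    v = len(vocab)
    iu = np.triu_indices(v, k=1)
    observed = joint[iu] > 0
    sparsity = float(observed.mean()) if observed.size else 0.0
    always = tuple(
        (vocab[i], vocab[j])
        for i, j in zip(*iu)
        if joint[i, j] > 0 and prob[i, j] == 1.0
    )
    return CooccurrenceResult(
        counts=pd.DataFrame(joint, index=vocab, columns=vocab),
        probability=pd.DataFrame(prob, index=vocab, columns=vocab),
        sparsity=sparsity,
        always_together=always,
    )


def frequent_groups(
    db: SceneDatabase,
    category: str,
    n: int,
    top_k: int = 10,
    min_support: int = 1,
) -> list[tuple[tuple[str, ...], int]]:
    """Top-k most frequent n-object groups within one category.

    Support is the number of the category's scenes containing every
    member of the group.  Counting is exact: each scene's distinct-label
    set is pruned to labels whose singleton support meets ``min_support``
    (anti-monotonicity guarantees no valid group is lost) and its
    n-subsets are enumerated.  Ties are broken by lexicographic group
    order.  Returns an empty list when no scene has ``n`` distinct
    (surviving) labels.
    """
    if n < 1:
        raise ValueError("group size must be >= 1")
    scenes = [set(s.labels) for s in db.scenes_of(category)]
    if not scenes:
        return []
    singleton = Counter(itertools.chain.from_iterable(scenes))
    keep = {l for l, c in singleton.items() if c >= min_support}
    support: Counter[tuple[str, ...]] = Counter()
    for items in scenes:
        pruned = sorted(items & keep)
        if len(pruned) >= n:
            support.update(itertools.combinations(pruned, n))
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(group, count) for group, count in ranked[:top_k]]


def group_diagnosticity(
    db: SceneDatabase, group: tuple[str, ...] | frozenset[str]
) -> pd.Series:
    """p(category | all group members present), per category.

    NaN for every category when no scene contains the full group.
    """
    members = set(group)
    if not members:
        raise ValueError("group must be non-empty")
    cats = db.categories
    joint = {c: 0 for c in cats}
    total = 0
    for scene in db.scenes:
        if members <= set(scene.labels):
            joint[scene.category] += 1
            total += 1
    if total == 0:
        return pd.Series({c: float("nan") for c in cats})
    return pd.Series({c: joint[c] / total for c in cats})


# ---------------------------------------------------------------------------
# Combinations, entropy, mutual information
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniqueCombinations:
    """Distinct object-presence sets and how often scenes share one."""

    n_unique: int
    fraction_unshared: float
    by_superordinate: dict[str, float]
    by_category: dict[str, float]


def unique_combinations(db: SceneDatabase) -> UniqueCombinations:
    """Count distinct presence sets and per-group unshared fractions.

    A scene's combination is "unshared" when no other scene in the whole
    database has exactly the same set of present labels.
    """
    combos = [frozenset(s.labels) for s in db.scenes]
    freq = Counter(combos)
    unshared = np.array([freq[c] == 1 for c in combos])
    sups = np.array(db.superordinate_labels())
    cats = np.array([s.category for s in db.scenes])
    by_sup = {
        s: float(unshared[sups == s].mean())
        for s in dict.fromkeys(db.taxonomy.values())
        if (sups == s).any()
    }
    by_cat = {
        c: float(unshared[cats == c].mean())
        for c in db.categories
        if (cats == c).any()
    }
    return UniqueCombinations(
        n_unique=len(freq),
        fraction_unshared=float(unshared.mean()) if len(combos) else 0.0,
        by_superordinate=by_sup,
        by_category=by_cat,
    )


def combination_count(vocabulary_size: int, k: int) -> int:
    """Exact number of k-object combinations from a vocabulary (C(V, k))."""
    if not 0 <= k <= vocabulary_size:
        raise ValueError(
            f"k={k} out of range for vocabulary of {vocabulary_size}"
        )
    return math.comb(vocabulary_size, k)


def database_entropy(db: SceneDatabase) -> tuple[float, float]:
    """Shannon entropy of the label distribution, in bits per object.

    ``p(o)`` is the instance count of each label divided by the total
    instance count.  Returns ``(entropy, log2(vocabulary size))``; the
    second value is the uniform-distribution upper bound.
    """
    counts = count_matrix(db).sum(axis=0).to_numpy(dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("database has no object instances")
    p = counts[counts > 0] / total
    entropy = float(-(p * np.log2(p)).sum())
    return entropy, math.log2(len(counts))


@dataclass(frozen=True)
class MITable:
    """Mutual information between object presence and category membership.

    ``binary`` is objects x categories: MI in bits between the binary
    presence variable O and the binary membership variable S for that
    category.  ``multiway`` is per object: MI between O and the full
    K-way category variable — the default ranking for "most informative
    overall".  ``binary_sum`` sums the per-category binary MI, the
    alternative overall ranking.
    """

    binary: pd.DataFrame
    multiway: pd.Series

    @property
    def binary_sum(self) -> pd.Series:
        return self.binary.sum(axis=1)

    def top_objects(self, k: int = 10, mode: str = "multiway") -> pd.Series:
        s = self.multiway if mode == "multiway" else self.binary_sum
        return s.sort_index().sort_values(ascending=False, kind="stable").head(k)

    def top_for(self, category: str, k: int = 10) -> pd.Series:
        col = self.binary[category]
        return col.sort_index().sort_values(ascending=False, kind="stable").head(k)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def mutual_information(db: SceneDatabase) -> MITable:
    """MI between binary object presence and scene category, in bits.

    The binary table treats each (object, category) pair as a 2x2
    contingency problem over scenes; the multiway series measures each
    object's information about the full category partition.  Both are
    plug-in estimates from observed proportions.
    """
    pres = presence_matrix(db)
    vocab = list(pres.columns)
    cats = db.categories
    N = len(db.scenes)
    cat_idx = pd.Series([s.category for s in db.scenes], index=pres.index)

    P = pres.to_numpy(dtype=float)  # scenes x V
    S = np.column_stack(
        [(cat_idx == c).to_numpy(dtype=float) for c in cats]
    )  # scenes x K

    n_o = P.sum(axis=0)  # V
    n_s = S.sum(axis=0)  # K
    joint = P.T @ S  # V x K: scenes with object AND in category

    p_os = joint / N
    p_o = n_o[:, None] / N
    p_s = n_s[None, :] / N

    # the four cells of each 2x2 table
    cells = [
        (p_os, p_o * p_s),
        (p_o - p_os, p_o * (1 - p_s)),
        (p_s - p_os, (1 - p_o) * p_s),
        (1 - p_o - p_s + p_os, (1 - p_o) * (1 - p_s)),
    ]
    mi = np.zeros_like(p_os)
    for p, indep in cells:
        p = np.clip(p, 0.0, 1.0)
        nz = (p > 0) & (indep > 0)
        mi[nz] += p[nz] * np.log2(p[nz] / indep[nz])
    mi = np.maximum(mi, 0.0)
    binary = pd.DataFrame(mi, index=vocab, columns=list(cats))

    # multiway: I(O; C) = H(C) + H(O) - H(O, C)
    pc = n_s / N
    h_c = -_xlogx(pc).sum()
    po = n_o / N
    h_o = -(_xlogx(po) + _xlogx(1 - po))
    joint_rows = np.stack([joint / N, (n_s[None, :] - joint) / N], axis=2)
    h_oc = -_xlogx(joint_rows).sum(axis=(1, 2))
    multiway = pd.Series(
        np.maximum(h_c + h_o - h_oc, 0.0), index=vocab, name="mi_multiway"
    )
    return MITable(binary=binary, multiway=multiway)
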
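"""Leave-one-out linear classification of scene representations.

Each representation (ensemble statistics, bag of words, quadrant
features) is evaluated with a linear maximum-margin classifier (libsvm
via scikit-learn: linear kernel, C = 1, one-vs-one multiclass voting) in
leave-one-out cross-validation: every scene is tested once by a model
trained on all remaining scenes.  Features are z-scored on each training
fold (the ensemble statistics mix scales — counts, area fractions,
normalized coordinates — so standardization is required for a meaningful
margin).

Auxiliary metrics: exact binomial tests against chance (6.25% for the
16-way basic-level task, 33% for the 3-way superordinate task),
macro-averaged one-vs-rest AUC from decision values, the nonparametric
sensitivity index A' derived per category from the confusion matrix, and
the Pearson correlation of off-diagonal confusion patterns between two
classifiers (or a classifier and human data).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from scenestats.annotation_io import SceneDatabase
from scenestats import bow as _bow
from scenestats.ensemble import (
    STATISTIC_GROUPS,
    FEATURE_NAMES,
    ensemble_feature_matrix,
)

__all__ = [
    "EvaluationReport",
    "loo_evaluate",
    "binomial_vs_chance",
    "a_prime",
    "SubsetResult",
    "feature_subset_experiment",
    "SweepResult",
    "ensemble_combination_sweep",
    "cross_database",
    "confusion_correlation",
    "ensemble_featurizer",
    "bow_featurizer",
]


def _make_classifier(C: float = 1.0) -> SVC:
    # libsvm: linear kernel, one-vs-one voting internally; 'ovr'-shaped
    # decision values are used only for AUC scoring.
    return SVC(kernel="linear", C=C, decision_function_shape="ovr")


@dataclass(frozen=True)
class EvaluationReport:
    """Classification outcome for one representation.

    ``confusion`` has true categories on rows, predictions on columns,
    in fixed sorted category order; row sums equal per-category scene
    counts and trace/total is the overall accuracy.
    """

    confusion: pd.DataFrame
    accuracy: float
    per_category_accuracy: pd.Series
    auc: float
    a_prime_per_category: pd.Series
    a_prime_mean: float
    chance: float
    p_vs_chance: float
    predictions: pd.Series = field(repr=False)

    @property
    def n_scenes(self) -> int:
        return int(self.confusion.to_numpy().sum())


def binomial_vs_chance(correct: int, total: int, chance: float) -> float:
    """Exact one-sided binomial p: P(X >= correct) under the chance rate."""
    if not 0 <= correct <= total:
        raise ValueError("correct must be within [0, total]")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must be in (0, 1)")
    return float(stats.binom.sf(correct - 1, total, chance))


def a_prime(hit_rate: float, false_alarm_rate: float) -> float:
    """Nonparametric sensitivity index A' from hit and false-alarm rates.

    A' = 0.5 + (H-F)(1+H-F) / (4H(1-F)) for H >= F, with the symmetric
    complement when F > H; 0.5 at H = F (chance), 1.0 at H=1, F=0.
    """
    H, F = float(hit_rate), float(false_alarm_rate)
    if not (0.0 <= H <= 1.0 and 0.0 <= F <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if H == F:
        return 0.5
    if H > F:
        return 0.5 + (H - F) * (1 + H - F) / (4 * H * (1 - F))
    return 0.5 - (F - H) * (1 + F - H) / (4 * F * (1 - H))


def _confusion_frame(
    y_true: Sequence[str], y_pred: Sequence[str], classes: list[str]
) -> pd.DataFrame:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return pd.DataFrame(m, index=classes, columns=classes)


def _a_prime_from_confusion(confusion: pd.DataFrame) -> pd.Series:
    """Per-category A' with one-vs-rest hit and false-alarm rates."""
    m = confusion.to_numpy(dtype=float)
    total = m.sum()
    out = {}
    for i, cat in enumerate(confusion.index):
        row = m[i].sum()
        hits = m[i, i]
        fas = m[:, i].sum() - hits
        H = hits / row if row else 0.0
        F = fas / (total - row) if total > row else 0.0
        out[cat] = a_prime(H, F)
    return pd.Series(out, name="a_prime")


def _build_report(
    y_true: list[str],
    y_pred: list[str],
    scores: np.ndarray | None,
    classes: list[str],
    chance: float | None = None,
) -> EvaluationReport:
    confusion = _confusion_frame(y_true, y_pred, classes)
    correct = int(np.trace(confusion.to_numpy()))
    total = len(y_true)
    accuracy = correct / total
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_cat = pd.Series(
            np.where(
                row_sums > 0, np.diag(confusion.to_numpy()) / row_sums, np.nan
            ),
            index=confusion.index,
            name="accuracy",
        )
    if chance is None:
        chance = 1.0 / len([c for c in classes if row_sums[c] > 0])
    auc = _macro_auc(y_true, scores, classes)
    ap = _a_prime_from_confusion(confusion)
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        per_category_accuracy=per_cat,
        auc=auc,
        a_prime_per_category=ap,
        a_prime_mean=float(ap.mean()),
        chance=chance,
        p_vs_chance=binomial_vs_chance(correct, total, chance),
        predictions=pd.Series(y_pred),
    )


def _macro_auc(
    y_true: list[str], scores: np.ndarray | None, classes: list[str]
) -> float:
    """Macro one-vs-rest AUC from decision values; NaN when undefined."""
    if scores is None:
        return float("nan")
    present = sorted(set(y_true))
    if len(present) < 2:
        return float("nan")
    if len(classes) == 2:
        y_bin = [1 if y == classes[1] else 0 for y in y_true]
        s = scores if scores.ndim == 1 else scores[:, 1]
        return float(roc_auc_score(y_bin, s))
    # one-vs-rest per class on raw decision values, macro-averaged over
    # the classes that have both positive and negative examples
    aucs = []
    y_arr = np.asarray(y_true, dtype=object)
    for j, c in enumerate(classes):
        pos = y_arr == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos.astype(int), scores[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def _map_level(
    labels: Sequence[str], level: str, taxonomy: dict[str, str] | None
) -> list[str]:
    if level == "basic":
        return list(labels)
    if level == "superordinate":
        if taxonomy is None:
            raise ValueError("superordinate level requires a taxonomy")
        return [taxonomy[l] for l in labels]
    raise ValueError(f"unknown level {level!r}")


def loo_evaluate(
    features: np.ndarray,
    labels: Sequence[str],
    *,
    level: str = "basic",
    taxonomy: dict[str, str] | None = None,
    C: float = 1.0,
) -> EvaluationReport:
    """Leave-one-out evaluation of a linear max-margin classifier.

    Every scene is held out once; the classifier (linear kernel, fixed
    C, one-vs-one voting) is refit on the remaining scenes with features
    z-scored on that training fold.  Deterministic given input order.
    With ``level="superordinate"`` the labels are first mapped through
    the taxonomy.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be (n_scenes, d) with d >= 1")
    y = _map_level(labels, level, taxonomy)
    if len(y) != X.shape[0]:
        raise ValueError("features and labels length mismatch")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 categories")
    counts = pd.Series(y).value_counts()
    singles = counts[counts == 1]
    if len(singles):
        warnings.warn(
            "categories with a single scene can never be predicted as "
            f"their own class in leave-one-out: {sorted(singles.index)}",
            stacklevel=2,
        )

    n = X.shape[0]
    preds: list[str] = []
    scores = np.zeros((n, len(classes)))
    y_arr = np.asarray(y, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_labels = set(y_arr[mask])
        if len(fold_labels) < 2:
            # degenerate fold: only one class remains to train on
            only = next(iter(fold_labels))
            preds.append(str(only))
            scores[i, classes.index(only)] = 1.0
            continue
        scaler = StandardScaler().fit(X[mask])
        clf = _make_classifier(C).fit(scaler.transform(X[mask]), y_arr[mask])
        xt = scaler.transform(X[i : i + 1])
        preds.append(str(clf.predict(xt)[0]))
        d = clf.decision_function(xt)
        if len(classes) == 2:
            scores[i, 1] = d.ravel()[0]
            scores[i, 0] = -scores[i, 1]
        else:
            # align the fold's class order with the global order
            fold_classes = list(clf.classes_)
            for j, c in enumerate(classes):
                scores[i, j] = d[0, fold_classes.index(c)]
    return _build_report(list(y), preds, scores, classes)


# ---------------------------------------------------------------------------
# Feature-subset experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubsetResult:
    accuracies: tuple[float, ...]
    mean: float
    ci95: tuple[float, float]
    k: int
    mode: str


def feature_subset_experiment(
    db: SceneDatabase,
    k: int,
    mode: str = "random",
    reps: int = 20,
    seed: int = 0,
    *,
    level: str = "basic",
) -> SubsetResult:
    """Bag-of-words classification with only ``k`` objects as features.

    ``mode="random"`` draws ``reps`` object subsets without replacement
    (seeded); ``mode="top_mi"`` takes the k objects with the highest
    overall (multiway) mutual information — a single deterministic run.
    Returns LOO accuracies with mean and 95% percentile interval.
    """
    counts = _bow.count_matrix(db)
    vocab = list(counts.columns)
    if k > len(vocab):
        raise ValueError(f"k={k} exceeds vocabulary size {len(vocab)}")
    labels = [s.category for s in db.scenes]
    taxonomy = dict(db.taxonomy)

    if mode == "top_mi":
        top = _bow.mutual_information(db).top_objects(k, mode="multiway")
        subsets = [list(top.index)]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        subsets = [
            list(np.asarray(vocab)[rng.choice(len(vocab), size=k, replace=False)])
            for _ in range(reps)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    accs = []
    for cols in subsets:
        rep = loo_evaluate(
            counts[cols].to_numpy(), labels, level=level, taxonomy=taxonomy
        )
        accs.append(rep.accuracy)
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return SubsetResult(
        accuracies=tuple(accs),
        mean=float(np.mean(accs)),
        ci95=(float(lo), float(hi)),
        k=k,
        mode=mode,
    )


@dataclass(frozen=True)
class SweepResult:
    """Mean LOO accuracy for every ensemble-statistic subset size."""

    per_size: dict[int, float]
    per_subset: dict[tuple[str, ...], float]
    slope: float  # accuracy gain per added statistic (least squares)
    r_squared: float


def ensemble_combination_sweep(
    db: SceneDatabase,
    sizes: Sequence[int] = (1, 2, 3, 4, 5, 6),
    *,
    level: str = "basic",
) -> SweepResult:
    """LOO accuracy of every subset of the six ensemble statistics.

    The two center-of-mass coordinates count as a single statistic.  For
    each subset size the accuracies over all subsets of that size are
    averaged, and a least-squares line is fit to (size, mean accuracy).
    """
    X, labels = ensemble_feature_matrix(db)
    taxonomy = dict(db.taxonomy)
    groups = list(STATISTIC_GROUPS)
    col_of = {name: i for i, name in enumerate(FEATURE_NAMES)}

    per_subset: dict[tuple[str, ...], float] = {}
    per_size: dict[int, float] = {}
    for size in sizes:
        accs = []
        for combo in itertools.combinations(groups, size):
            cols = [col_of[f] for g in combo for f in STATISTIC_GROUPS[g]]
            rep = loo_evaluate(
                X[:, cols], labels, level=level, taxonomy=taxonomy
            )
            per_subset[combo] = rep.accuracy
            accs.append(rep.accuracy)
        per_size[size] = float(np.mean(accs))

    xs = np.array(list(per_size), dtype=float)
    ys = np.array([per_size[s] for s in per_size])
    if len(xs) >= 2 and np.ptp(ys) > 0:
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        r2 = 1.0 - resid.var() / ys.var()
    elif len(xs) >= 2:
        slope, r2 = 0.0, 1.0
    else:
        slope, r2 = float("nan"), float("nan")
    return SweepResult(
        per_size=per_size,
        per_subset=per_subset,
        slope=float(slope),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# Cross-database transfer
# ---------------------------------------------------------------------------

Featurizer = Callable[[SceneDatabase, list[str] | None], np.ndarray]


def ensemble_featurizer(db: SceneDatabase, vocab: list[str] | None = None) -> np.ndarray:
    X, _ = ensemble_feature_matrix(db)
    return X


def bow_featurizer(db: SceneDatabase, vocab: list[str] | None = None) -> np.ndarray:
    """Count-matrix features on a shared vocabulary (union) column order."""
    counts = _bow.count_matrix(db)
    if vocab is not None:
        counts = counts.reindex(columns=vocab, fill_value=0)
    return counts.to_numpy()


def cross_database(
    train: SceneDatabase,
    test: SceneDatabase,
    featurizer: Featurizer = ensemble_featurizer,
    *,
    level: str = "basic",
    C: float = 1.0,
) -> EvaluationReport:
    """Train once on one database, predict every scene of another.

    The featurizer maps both databases into a single feature space (for
    bag of words, the union vocabulary).  Features are z-scored on the
    training set.  Test categories absent from the training set can never
    be predicted (warned).
    """
    vocab = sorted(set(train.vocabulary) | set(test.vocabulary))
    X_train = featurizer(train, vocab)
    X_test = featurizer(test, vocab)
    y_train = _map_level(
        [s.category for s in train.scenes], level, dict(train.taxonomy)
    )
    y_test = _map_level(
        [s.category for s in test.scenes], level, dict(test.taxonomy)
    )
    missing = sorted(set(y_test) - set(y_train))
    if missing:
        warnings.warn(
            f"test categories absent from training set: {missing}",
            stacklevel=2,
        )
    classes = sorted(set(y_train) | set(y_test))
    scaler = StandardScaler().fit(X_train)
    clf = _make_classifier(C).fit(scaler.transform(X_train), y_train)
    Xt = scaler.transform(X_test)
    preds = [str(p) for p in clf.predict(Xt)]

    train_classes = list(clf.classes_)
    d = clf.decision_function(Xt)
    scores = None
    if set(classes) == set(train_classes):
        if len(classes) == 2:
            scores = np.column_stack([-d.ravel(), d.ravel()])
        else:
            order = [train_classes.index(c) for c in classes]
            scores = d[:, order]
    chance = 1.0 / len(sorted(set(y_test)))
    return _build_report(y_test, preds, scores, classes, chance=chance)


# ---------------------------------------------------------------------------
# Confusion-pattern correlation
# ---------------------------------------------------------------------------


def _aggregate_superordinate(
    confusion: pd.DataFrame, taxonomy: dict[str, str]
) -> pd.DataFrame:
    sups = sorted(set(taxonomy[c] for c in confusion.index))
    out = pd.DataFrame(0, index=sups, columns=sups, dtype=float)
    for t in confusion.index:
        for p in confusion.columns:
            out.loc[taxonomy[t], taxonomy[p]] += confusion.loc[t, p]
    return out


def confusion_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    *,
    level: str = "basic",
    taxonomy: dict[str, str] | None = None,
) -> float:
    """Pearson r between the off-diagonal error patterns of two confusions.

    Rows are first normalized to proportions; at the superordinate level
    cells are aggregated through the taxonomy before normalizing.  NaN
    when either error pattern has zero variance.
    """
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("confusion matrices must share the same category order")
    if level == "superordinate":
        if taxonomy is None:
            raise ValueError("superordinate level requires a taxonomy")
        a = _aggregate_superordinate(a, taxonomy)
        b = _aggregate_superordinate(b, taxonomy)

    def offdiag(m: pd.DataFrame) -> np.ndarray:
        arr = m.to_numpy(dtype=float)
        sums = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, arr / sums, 0.0)
        mask = ~np.eye(len(m), dtype=bool)
        return norm[mask]

    x, y = offdiag(a), offdiag(b)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])
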
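"""Bag-of-words statistics: frequencies, diagnosticity, groups, information."""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from scenestats import SceneDatabase, bow

from conftest import make_scene


class TestCountMatrix:
    def test_instance_counts(self, three_cat_db):
        m = bow.count_matrix(three_cat_db)
        assert m.loc["k2", "wall"] == 2
        assert m.loc["k2", "sink"] == 1
        assert m.loc["c1", "wall"] == 0

    def test_column_sums_match_direct_scan(self, recovery_db_small):
        m = bow.count_matrix(recovery_db_small)
        direct = Counter(
            l for s in recovery_db_small.scenes for l in s.labels
        )
        for obj in m.columns:
            assert m[obj].sum() == direct[obj]

    def test_disjoint_scenes_have_disjoint_columns(self):
        db = SceneDatabase(
            (
                make_scene("a", "kitchen", ["x", "y"]),
                make_scene("b", "kitchen", ["z"]),
            ),
            {"kitchen": "indoor"},
        )
        m = bow.count_matrix(db)
        assert (m.loc["a"] > 0).sum() == 2 and (m.loc["b"] > 0).sum() == 1
        assert not ((m.loc["a"] > 0) & (m.loc["b"] > 0)).any()


class TestObjectFrequency:
    def test_always_present_object(self, three_cat_db):
        per_cat, overall = bow.object_frequency(three_cat_db)
        assert per_cat.loc["sink", "kitchen"] == 1.0
        assert per_cat.loc["wall", "street"] == 0.5
        assert overall.loc["wall", "n_scenes"] == 3
        assert overall.loc["wall", "n_instances"] == 4

    def test_frequencies_recover_generator_probabilities(self, default_db):
        # 20 scenes/category: loose Monte-Carlo band, still detects a
        # broken presence-sampling scheme
        from scenestats import default_profiles

        per_cat, _ = bow.object_frequency(default_db)
        p = {pr.category: pr for pr in default_profiles()}["coast"]
        for label, prob in p.object_probs.items():
            if prob > 0.3:
                assert per_cat.loc[label, "coast"] == pytest.approx(
                    prob, abs=0.3
                )


class TestRankFrequency:
    def test_equal_counts_slope_zero(self):
        db = SceneDatabase(
            (make_scene("s", "kitchen", ["a", "b", "c", "d"]),),
            {"kitchen": "indoor"},
        )
        _, slope = bow.rank_frequency(db)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_zipf_slope_minus_one(self):
        counts = np.array([1200 // r for r in range(1, 41)], dtype=float)
        # use exact c/r values rather than integer division artifacts
        counts = 1200.0 / np.arange(1, 41)
        assert bow.zipf_slope(counts) == pytest.approx(-1.0, abs=1e-12)

    def test_table_sorted_descending(self, three_cat_db):
        table, _ = bow.rank_frequency(three_cat_db)
        assert (np.diff(table["count"].to_numpy()) <= 0).all()
        assert list(table["rank"]) == list(range(1, len(table) + 1))


class TestDiagnosticity:
    def test_exclusive_object(self, three_cat_db):
        diag = bow.diagnosticity(three_cat_db)
        assert diag.table.loc["sink", "kitchen"] == 1.0
        assert diag.table.loc["sink", "coast"] == 0.0

    def test_uniform_spread(self):
        scenes = tuple(
            make_scene(f"{c}{i}", c, ["wall"])
            for c in ("kitchen", "street", "coast")
            for i in range(2)
        )
        db = SceneDatabase(
            scenes,
            {"kitchen": "indoor", "street": "urban", "coast": "natural"},
        )
        diag = bow.diagnosticity(db)
        for c in db.categories:
            assert diag.table.loc["wall", c] == pytest.approx(1 / 3)

    def test_hand_counts(self, three_cat_db):
        diag = bow.diagnosticity(three_cat_db)
        # wall in k1, k2, s1 -> support 3, kitchen share 2/3
        assert diag.support["wall"] == 3
        assert diag.table.loc["wall", "kitchen"] == pytest.approx(2 / 3)
        assert diag.table.loc["wall", "street"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self, recovery_db_small):
        diag = bow.diagnosticity(recovery_db_small)
        np.testing.assert_allclose(diag.table.sum(axis=1).to_numpy(), 1.0)

    def test_support_filter(self, three_cat_db):
        diag = bow.diagnosticity(three_cat_db, min_instances=3)
        assert list(diag.filtered().index) == ["wall"]
        assert "sink" in diag.table.index  # still computable unfiltered


class TestLandmarkDiagnosticity:
    def test_single_category_database(self):
        scenes = tuple(
            make_scene(f"k{i}", "kitchen", ["sink", "wall"]) for i in range(3)
        )
        db = SceneDatabase(scenes, {"kitchen": "indoor"})
        for mode in ("largest", "most_central"):
            lm = bow.landmark_object_diagnosticity(db, mode)
            assert lm.mean == 1.0

    def test_area_tie_breaks_to_smaller_label(self):
        db = SceneDatabase(
            (make_scene("k", "kitchen", ["zeta", "alpha"]),),
            {"kitchen": "indoor"},
        )
        lm = bow.landmark_object_diagnosticity(db, "largest")
        assert lm.objects["k"] == "alpha"

    def test_mean_matches_bruteforce(self, recovery_db_small):
        from scenestats.annotation_io import polygon_area

        lm = bow.landmark_object_diagnosticity(recovery_db_small, "largest")
        diag = bow.diagnosticity(recovery_db_small).table
        vals = []
        for scene in recovery_db_small.scenes:
            best = min(
                scene.objects,
                key=lambda o: (-polygon_area(o.polygon), o.label),
            )
            vals.append(diag.loc[best.label, scene.category])
        assert lm.mean == pytest.approx(np.mean(vals), rel=1e-12)


class TestSpecificity:
    def test_single_scene_object(self, three_cat_db):
        spec = bow.specificity(three_cat_db)
        assert spec["stove"] == 1
        assert spec["wall"] == 2  # kitchen and street

    def test_matches_direct_set_count(self, recovery_db_small):
        spec = bow.specificity(recovery_db_small)
        for obj in ("bg00", "kitchen_marker0"):
            direct = len(
                {
                    s.category
                    for s in recovery_db_small.scenes
                    if obj in s.labels
                }
            )
            assert spec[obj] == direct

    def test_histogram_totals(self, three_cat_db):
        spec = bow.specificity(three_cat_db)
        hist = bow.specificity_histogram(spec, 3)
        assert hist.sum() == len(three_cat_db.vocabulary)


class TestCooccurrence:
    def test_always_together(self, three_cat_db):
        cooc = bow.cooccurrence(three_cat_db)
        # sky and ocean co-occur in both coast scenes and nowhere else
        assert cooc.probability.loc["sky", "ocean"] == 1.0
        assert ("ocean", "sky") in cooc.always_together

    def test_never_copresent(self, three_cat_db):
        cooc = bow.cooccurrence(three_cat_db)
        assert cooc.counts.loc["sink", "sky"] == 0

    def test_matches_bruteforce_pairs(self, three_cat_db):
        cooc = bow.cooccurrence(three_cat_db)
        sets = [set(s.labels) for s in three_cat_db.scenes]
        vocab = three_cat_db.vocabulary
        for a, b in itertools.combinations(vocab, 2):
            joint = sum(1 for s in sets if a in s and b in s)
            either = sum(1 for s in sets if a in s or b in s)
            assert cooc.counts.loc[a, b] == joint
            expected = joint / either if either else 0.0
            assert cooc.probability.loc[a, b] == pytest.approx(expected)

    def test_sparsity_fraction(self, three_cat_db):
        cooc = bow.cooccurrence(three_cat_db)
        sets = [set(s.labels) for s in three_cat_db.scenes]
        vocab = three_cat_db.vocabulary
        observed = sum(
            1
            for a, b in itertools.combinations(vocab, 2)
            if any(a in s and b in s for s in sets)
        )
        total = math.comb(len(vocab), 2)
        assert cooc.sparsity == pytest.approx(observed / total)


class TestFrequentGroups:
    FIXTURE = [
        ["a", "b", "c"],
        ["a", "b", "c", "d"],
        ["a", "b", "d"],
        ["b", "c", "d"],
        ["a", "c"],
    ]

    def _db(self):
        scenes = tuple(
            make_scene(f"s{i}", "kitchen", labels)
            for i, labels in enumerate(self.FIXTURE)
        )
        return SceneDatabase(scenes, {"kitchen": "indoor"})

    def test_n1_reduces_to_most_frequent_object(self):
        groups = bow.frequent_groups(self._db(), "kitchen", 1, top_k=1)
        assert groups[0] == (("a",), 4) or groups[0] == (("b",), 4)
        # tie between a and b at support 4 -> lexicographic
        assert groups[0][0] == ("a",)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, n):
        db = self._db()
        groups = dict(bow.frequent_groups(db, "kitchen", n, top_k=100))
        exhaustive: Counter = Counter()
        for labels in self.FIXTURE:
            exhaustive.update(itertools.combinations(sorted(set(labels)), n))
        assert groups == {g: c for g, c in exhaustive.items()}

    def test_anti_monotone_support(self):
        db = self._db()
        sup2 = dict(bow.frequent_groups(db, "kitchen", 2, top_k=100))
        sup3 = dict(bow.frequent_groups(db, "kitchen", 3, top_k=100))
        for group, support in sup3.items():
            for sub in itertools.combinations(group, 2):
                assert support <= sup2[sub]

    def test_oversized_group_empty(self):
        assert bow.frequent_groups(self._db(), "kitchen", 6) == []

    def test_semantics_on_synthetic(self, recovery_db_small):
        groups = bow.frequent_groups(recovery_db_small, "kitchen", 3, top_k=5)
        assert all(len(g) == 3 for g, _ in groups)
        assert all(c >= 1 for _, c in groups)


class TestGroupDiagnosticity:
    def test_category_unique_group(self, three_cat_db):
        gd = bow.group_diagnosticity(three_cat_db, ("sink", "stove"))
        assert gd["kitchen"] == 1.0

    def test_hand_ratio(self, three_cat_db):
        gd = bow.group_diagnosticity(three_cat_db, ("wall",))
        assert gd["kitchen"] == pytest.approx(2 / 3)
        assert gd["street"] == pytest.approx(1 / 3)

    def test_unseen_group_flagged(self, three_cat_db):
        gd = bow.group_diagnosticity(three_cat_db, ("sink", "sky"))
        assert gd.isna().all()

    def test_superset_at_least_singleton_on_fixture(self, three_cat_db):
        single = bow.group_diagnosticity(three_cat_db, ("sink",))["kitchen"]
        pair = bow.group_diagnosticity(three_cat_db, ("sink", "stove"))["kitchen"]
        assert pair >= single


class TestUniqueCombinations:
    def test_all_identical(self):
        scenes = tuple(
            make_scene(f"s{i}", "kitchen", ["a", "b"]) for i in range(4)
        )
        db = SceneDatabase(scenes, {"kitchen": "indoor"})
        uc = bow.unique_combinations(db)
        assert uc.n_unique == 1
        assert uc.fraction_unshared == 0.0

    def test_all_distinct(self, three_cat_db):
        uc = bow.unique_combinations(three_cat_db)
        assert uc.n_unique == 6
        assert uc.fraction_unshared == 1.0

    def test_matches_hashset_oracle(self, recovery_db_small):
        uc = bow.unique_combinations(recovery_db_small)
        combos = [frozenset(s.labels) for s in recovery_db_small.scenes]
        assert uc.n_unique == len(set(combos))
        assert uc.n_unique <= len(recovery_db_small.scenes)
        freq = Counter(combos)
        unshared = sum(1 for c in combos if freq[c] == 1)
        assert uc.fraction_unshared == pytest.approx(unshared / len(combos))

    def test_multiset_ignored_presence_only(self):
        db = SceneDatabase(
            (
                make_scene("a", "kitchen", ["x", "x", "y"]),
                make_scene("b", "kitchen", ["x", "y"]),
            ),
            {"kitchen": "indoor"},
        )
        assert bow.unique_combinations(db).n_unique == 1


class TestCombinationCount:
    @pytest.mark.parametrize(
        "n,k,expected", [(5, 0, 1), (5, 2, 10), (10, 10, 1), (0, 0, 1)]
    )
    def test_small_values(self, n, k, expected):
        assert bow.combination_count(n, k) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bow.combination_count(5, 6)
        with pytest.raises(ValueError):
            bow.combination_count(5, -1)


class TestEntropy:
    def test_single_object_type(self):
        db = SceneDatabase(
            (make_scene("s", "kitchen", ["wall", "wall"]),),
            {"kitchen": "indoor"},
        )
        entropy, limit = bow.database_entropy(db)
        assert entropy == 0.0
        assert limit == 0.0  # log2(1)

    def test_closed_form_distribution(self):
        # probabilities (1/2, 1/4, 1/8, 1/8) -> 1.75 bits
        labels = ["a"] * 4 + ["b"] * 2 + ["c"] + ["d"]
        db = SceneDatabase(
            (make_scene("s", "kitchen", labels),), {"kitchen": "indoor"}
        )
        entropy, limit = bow.database_entropy(db)
        assert entropy == pytest.approx(1.75)
        assert limit == pytest.approx(2.0)

    def test_bounded_by_uniform_limit(self, default_db):
        entropy, limit = bow.database_entropy(default_db)
        assert 0 < entropy <= limit


class TestMutualInformation:
    def test_perfect_association_one_bit(self):
        scenes = tuple(
            [make_scene(f"k{i}", "kitchen", ["sink"]) for i in range(4)]
            + [make_scene(f"c{i}", "coast", ["sky"]) for i in range(4)]
        )
        db = SceneDatabase(
            scenes, {"kitchen": "indoor", "coast": "natural"}
        )
        mi = bow.mutual_information(db)
        assert mi.binary.loc["sink", "kitchen"] == pytest.approx(1.0)

    def test_independence_zero_bits(self):
        scenes = tuple(
            make_scene(f"{c}{i}", c, ["wall"])
            for c in ("kitchen", "coast")
            for i in range(3)
        )
        db = SceneDatabase(
            scenes, {"kitchen": "indoor", "coast": "natural"}
        )
        mi = bow.mutual_information(db)
        assert mi.binary.loc["wall", "kitchen"] == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_everywhere(self, recovery_db_small):
        mi = bow.mutual_information(recovery_db_small)
        assert (mi.binary.to_numpy() >= 0).all()
        assert (mi.multiway.to_numpy() >= 0).all()

    def test_exclusive_markers_top_rankings(self, recovery_db_small):
        mi = bow.mutual_information(recovery_db_small)
        diag = bow.diagnosticity(recovery_db_small)
        for cat in ("kitchen", "coast", "office"):
            markers = {f"{cat}_marker{i}" for i in range(3)}
            assert set(mi.top_for(cat, 3).index) == markers
            top_diag = diag.table[cat].sort_values(ascending=False).head(3)
            assert set(top_diag.index) == markers
            np.testing.assert_allclose(top_diag.to_numpy(), 1.0)
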
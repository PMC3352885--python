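import itertools

import numpy as np
import pytest

from taxocat.catalog import CatalogError
from taxocat.distinctness import (
    DistinctnessResult,
    build_classification_tree,
    distinctness_by_order,
    distinctness_regression,
    overlay_groups,
    pairwise_distance,
    taxonomic_distinctness,
)

from conftest import build_catalog, random_catalog


def brute_force_delta_plus(tree, group):
    """Independent Δ+ oracle: explicit double loop over all species pairs."""
    idx = [i for i in range(tree.n_species) if tree.orders[i] == group]
    if len(idx) < 2:
        return 0.0
    d_genus, d_family, d_order, d_class = tree.cumulative_distances
    total, pairs = 0.0, 0
    for i, j in itertools.combinations(idx, 2):
        if tree.orders[i] != tree.orders[j]:
            total += d_class
        elif tree.families[i] != tree.families[j]:
            total += d_order
        elif tree.genera[i] != tree.genera[j]:
            total += d_family
        else:
            total += d_genus
        pairs += 1
    return total / pairs


class TestTreeConstruction:
    def test_node_count_sums_ranks(self):
        cat = build_catalog(
            [
                ("O", "F", "G1", "a"),
                ("O", "F", "G1", "b"),
                ("O", "F", "G2", "c"),
            ]
        )
        tree = build_classification_tree(cat)
        # root + 1 order + 1 family + 2 genera + 3 species
        assert tree.n_nodes == 8

    def test_single_species_is_a_five_node_chain(self):
        tree = build_classification_tree(build_catalog([("O", "F", "G", "a")]))
        assert tree.n_nodes == 5

    def test_unplaced_species_rejected(self):
        cat = build_catalog([("O", "", "G", "a")])
        with pytest.raises(CatalogError, match="placeholder"):
            build_classification_tree(cat)

    def test_equal_steps_sum_to_max_path(self):
        tree = build_classification_tree(build_catalog([("O", "F", "G", "a")]))
        assert tree.step_lengths == (25.0, 25.0, 25.0, 25.0)

    def test_variable_steps_rescaled(self):
        tree = build_classification_tree(
            build_catalog([("O", "F", "G", "a")]), step_lengths=(1, 2, 3, 4)
        )
        assert sum(tree.step_lengths) == pytest.approx(100.0)
        assert tree.step_lengths[0] == pytest.approx(10.0)


class TestPairwiseDistance:
    @pytest.fixture
    def tree(self):
        return build_classification_tree(
            build_catalog(
                [
                    ("O1", "F1", "G1", "a"),
                    ("O1", "F1", "G1", "b"),
                    ("O1", "F1", "G2", "c"),
                    ("O1", "F2", "G3", "d"),
                    ("O2", "F3", "G4", "e"),
                ]
            )
        )

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("G1 a", "G1 b", 25.0),  # congeners
            ("G1 a", "G2 c", 50.0),  # confamilial
            ("G1 a", "G3 d", 75.0),  # con-ordinal
            ("G1 a", "G4 e", 100.0),  # different orders
            ("G1 a", "G1 a", 0.0),  # self
        ],
    )
    def test_distance_by_lowest_shared_rank(self, tree, a, b, expected):
        assert pairwise_distance(tree, a, b) == expected
        assert pairwise_distance(tree, b, a) == expected

    def test_unknown_species_errors(self, tree):
        with pytest.raises(KeyError):
            pairwise_distance(tree, "G1 a", "G9 zz")


class TestDeltaPlus:
    def test_two_congeners_score_one_step(self):
        tree = build_classification_tree(
            build_catalog([("O", "F", "G", "a"), ("O", "F", "G", "b")])
        )
        assert taxonomic_distinctness(tree, "O").delta_plus == 25.0

    def test_singleton_group_scores_zero(self):
        tree = build_classification_tree(build_catalog([("O", "F", "G", "a")]))
        res = taxonomic_distinctness(tree, "O")
        assert res.s == 1
        assert res.delta_plus == 0.0

    def test_three_species_mixed_ranks_average(self):
        # pairwise distances 25 (congeneric), 50, 50 -> hand mean 41.666..
        cat = build_catalog(
            [("O", "F", "G1", "a"), ("O", "F", "G1", "b"), ("O", "F", "G2", "c")]
        )
        tree = build_classification_tree(cat)
        assert taxonomic_distinctness(tree, "O").delta_plus == pytest.approx(125 / 3)

    def test_unknown_group_errors(self):
        tree = build_classification_tree(build_catalog([("O", "F", "G", "a")]))
        with pytest.raises(KeyError):
            taxonomic_distinctness(tree, "Nope")

    def test_matches_brute_force_oracle_on_random_catalogs(self, rng):
        for _ in range(12):
            cat = random_catalog(rng, max_species=80)
            tree = build_classification_tree(cat)
            for res in distinctness_by_order(tree):
                oracle = brute_force_delta_plus(tree, res.group_name)
                assert res.delta_plus == pytest.approx(oracle, abs=1e-9)

    def test_bounds_and_floor(self, rng):
        for _ in range(10):
            tree = build_classification_tree(random_catalog(rng, max_species=50))
            for res in distinctness_by_order(tree):
                assert 0 <= res.delta_plus <= tree.max_path
                if res.s >= 2:
                    assert res.delta_plus >= 25.0

    def test_merging_genera_never_increases_delta_plus(self, rng):
        for _ in range(10):
            cat = random_catalog(rng, max_species=60)
            tree = build_classification_tree(cat)
            # relabel one genus as a confamilial sibling, where one exists
            fams = {}
            for i in range(tree.n_species):
                fams.setdefault((tree.orders[i], tree.families[i]), set()).add(
                    tree.genera[i]
                )
            target = next((k for k, v in fams.items() if len(v) >= 2), None)
            if target is None:
                continue
            g_keep, g_merge = sorted(fams[target])[:2]
            merged_rows = []
            for i in range(tree.n_species):
                g = tree.genera[i]
                if (tree.orders[i], tree.families[i]) == target and g == g_merge:
                    g = g_keep
                merged_rows.append(
                    (tree.orders[i], tree.families[i], g, f"s{i}")
                )
            merged = build_classification_tree(build_catalog(merged_rows))
            order = target[0]
            before = taxonomic_distinctness(tree, order).delta_plus
            after = taxonomic_distinctness(merged, order).delta_plus
            assert after <= before + 1e-12

    def test_scale_equivariance(self, rng):
        cat = random_catalog(rng, max_species=40)
        t100 = build_classification_tree(cat, max_path=100)
        t200 = build_classification_tree(cat, max_path=200)
        for r100, r200 in zip(distinctness_by_order(t100), distinctness_by_order(t200)):
            assert r200.delta_plus == pytest.approx(2 * r100.delta_plus)


class TestRegression:
    def test_collinear_points_have_unit_r_squared(self):
        pts = [
            DistinctnessResult("a", 10, 10.0),
            DistinctnessResult("b", 100, 20.0),
            DistinctnessResult("c", 1000, 30.0),
        ]
        assert distinctness_regression(pts).r_squared == pytest.approx(1.0)

    def test_toy_r_squared_matches_hand_computation(self):
        # {(1,10),(2,20),(3,25)}: r² = Sxy²/(Sxx·Syy) = 15²/(2·116.667) = 0.9643
        pts = [
            DistinctnessResult("a", 10, 10.0),
            DistinctnessResult("b", 100, 20.0),
            DistinctnessResult("c", 1000, 25.0),
        ]
        fit = distinctness_regression(pts)
        assert fit.r_squared == pytest.approx(225 / (2 * (350 / 3)), abs=1e-4)

    def test_small_groups_excluded_by_name(self):
        pts = [DistinctnessResult(f"g{i}", 10 * (i + 1), 50.0 + i) for i in range(4)]
        pts.append(DistinctnessResult("tiny", 2, 25.0))
        fit = distinctness_regression(pts, min_species=4)
        assert fit.excluded_groups == ("tiny",)
        assert fit.n_points == 4

    def test_too_few_points_errors(self):
        pts = [DistinctnessResult("a", 10, 10.0), DistinctnessResult("b", 100, 20.0)]
        with pytest.raises(ValueError):
            distinctness_regression(pts)

    def test_r_squared_invariant_under_affine_richness_rescale(self, rng):
        pts = [
            DistinctnessResult(f"g{i}", int(10 ** (1 + 2 * rng.random())), 40 + 40 * rng.random())
            for i in range(8)
        ]
        fit1 = distinctness_regression(pts)
        # multiplying every s by a constant shifts log10(s) by a constant
        pts2 = [
            DistinctnessResult(r.group_name, r.s * 100, r.delta_plus) for r in pts
        ]
        fit2 = distinctness_regression(pts2)
        assert fit2.r_squared == pytest.approx(fit1.r_squared, abs=1e-12)
        assert fit2.slope == pytest.approx(fit1.slope, abs=1e-9)


class TestOverlay:
    def test_point_on_line_classified_on(self):
        pts = [
            DistinctnessResult("a", 10, 10.0),
            DistinctnessResult("b", 100, 20.0),
            DistinctnessResult("c", 1000, 30.0),
        ]
        fit = distinctness_regression(pts)
        report = overlay_groups(fit, [DistinctnessResult("x", 100, 20.0)])
        assert report.groups[0].sign == "on"
        assert report.groups[0].residual == pytest.approx(0.0, abs=1e-9)

    def test_overlay_does_not_alter_fit(self):
        pts = [
            DistinctnessResult("a", 10, 12.0),
            DistinctnessResult("b", 100, 18.0),
            DistinctnessResult("c", 1000, 33.0),
        ]
        fit = distinctness_regression(pts)
        report = overlay_groups(fit, [DistinctnessResult("x", 50, 99.0)])
        assert report.fit is fit
        assert report.groups[0].sign == "above"
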
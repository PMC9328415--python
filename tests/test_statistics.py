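"""Statistics: heights, branch-length means, distances, MRCA, treeness,
Gamma, minimum leaf distances — each against an independent oracle."""

import itertools
import math
import random

import pytest

from phylokit import (LabelLookupError, LcaIndex, NotUltrametricError,
                      Node, Tree, UndefinedStatisticError, avg_branch_length,
                      distance_between, distance_matrix, gamma_computation,
                      gamma_statistic, height, min_leaf_distances, mrca,
                      random_tree, read_tree_newick, treeness)

from conftest import (brute_distance, brute_mrca, gamma_oracle,
                      leaf_depth_walk, random_trees)


class TestHeight:
    def test_hand_example(self, small_tree):
        assert height(small_tree) == pytest.approx(4.0)  # max(2, 4, 1)

    def test_all_lengths_absent_is_zero(self):
        assert height(read_tree_newick("((A,B)X,C)R;")) == 0.0

    @pytest.mark.parametrize("tree", random_trees(6, 64),
                             ids=lambda t: f"n{t.num_nodes()[0]}")
    def test_matches_per_leaf_path_walk(self, tree):
        expected = max(leaf_depth_walk(l) for l in tree.traverse_leaves())
        assert height(tree) == pytest.approx(expected, abs=1e-12)


class TestAvgBranchLength:
    def test_three_classes(self):
        tree = read_tree_newick("((A:1,B:3)X:2,C:6)R;")
        assert avg_branch_length(tree, "all") == pytest.approx(3.0)
        assert avg_branch_length(tree, "internal") == pytest.approx(2.0)
        assert avg_branch_length(tree, "leaf") == pytest.approx(10 / 3)

    def test_absent_lengths_excluded_not_zeroed(self):
        tree = read_tree_newick("((A:1,B)X:2,C:6)R;")  # B unmeasured
        assert avg_branch_length(tree, "leaf") == pytest.approx(3.5)

    def test_no_qualifying_edges_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            avg_branch_length(read_tree_newick("((A,B)X,C)R;"), "all")


class TestDistances:
    def test_identity_and_hand_pair(self):
        tree = read_tree_newick("((A:1,B:1)X:1,C:2)R;")
        a, b = tree.leaf_map()["A"], tree.leaf_map()["B"]
        assert distance_between(tree, a, a) == 0.0
        assert distance_between(tree, a, b) == pytest.approx(2.0)

    def test_matrix_single_pair(self):
        matrix = distance_matrix(read_tree_newick("(A:1,B:2);"))
        assert matrix["A", "B"] == pytest.approx(3.0)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(LabelLookupError):
            distance_matrix(read_tree_newick("((A:1,A:2)X:1,C:1)R;"))

    @pytest.mark.parametrize("tree", random_trees(10, 64, seed0=5),
                             ids=lambda t: f"n{t.num_nodes()[1]}leaves")
    def test_matrix_equals_bruteforce_and_identity(self, tree):
        matrix = distance_matrix(tree)
        leaf_nodes = tree.leaf_map()
        labels = matrix.labels
        rng = random.Random(1)
        pairs = [(a, b) for a in labels for b in labels]
        for a, b in rng.sample(pairs, min(300, len(pairs))):
            expected = brute_distance(leaf_nodes[a], leaf_nodes[b])
            assert matrix[a, b] == pytest.approx(expected, abs=1e-9)
            assert distance_between(tree, leaf_nodes[a], leaf_nodes[b]) == \
                pytest.approx(expected, abs=1e-9)
            # depth/MRCA identity
            anc = brute_mrca(leaf_nodes[a], leaf_nodes[b])
            ident = (leaf_depth_walk(leaf_nodes[a]) +
                     leaf_depth_walk(leaf_nodes[b]) -
                     2 * leaf_depth_walk(anc))
            assert matrix[a, b] == pytest.approx(ident, abs=1e-9)

    @pytest.mark.parametrize("tree", random_trees(5, 48, seed0=13),
                             ids=lambda t: f"n{t.num_nodes()[1]}leaves")
    def test_tree_metric_axioms(self, tree):
        matrix = distance_matrix(tree)
        m = matrix.matrix
        n = len(matrix)
        assert (m.diagonal() == 0).all()
        assert abs(m - m.T).max() < 1e-12
        rng = random.Random(0)
        for _ in range(100):
            i, j, k = (rng.randrange(n) for _ in range(3))
            assert m[i, j] <= m[i, k] + m[k, j] + 1e-9
        if n >= 4:
            for _ in range(100):
                i, j, k, l = rng.sample(range(n), 4)
                sums = sorted([m[i, j] + m[k, l], m[i, k] + m[j, l],
                               m[i, l] + m[j, k]])
                assert sums[2] - sums[1] < 1e-9  # four-point condition

    def test_ultrametric_identity(self):
        tree = random_tree(40, "coalescent", seed=21)
        matrix = distance_matrix(tree)
        h = height(tree)
        leaf_nodes = tree.leaf_map()
        for a, b in itertools.islice(
                itertools.combinations(matrix.labels, 2), 200):
            anc = brute_mrca(leaf_nodes[a], leaf_nodes[b])
            expected = 2 * (h - leaf_depth_walk(anc))
            assert matrix[a, b] == pytest.approx(expected, abs=1e-9)


class TestMrca:
    def test_singleton_is_the_leaf(self, small_tree):
        assert mrca(small_tree, ["A"]) is small_tree.leaf_map()["A"]

    def test_hand_examples(self):
        tree = read_tree_newick("((A,B)X,C)R;")
        assert mrca(tree, ["A", "B"]).label == "X"
        assert mrca(tree, ["A", "C"]).label == "R"

    def test_unknown_label_is_error(self, small_tree):
        with pytest.raises(LabelLookupError):
            mrca(small_tree, ["A", "ghost"])

    @pytest.mark.parametrize("tree", random_trees(6, 64, seed0=8),
                             ids=lambda t: f"n{t.num_nodes()[1]}leaves")
    def test_equals_ancestor_set_oracle_all_pairs(self, tree):
        leaf_nodes = tree.leaf_map()
        index = LcaIndex(tree)
        labels = list(leaf_nodes)
        for a, b in itertools.combinations(labels, 2):
            expected = brute_mrca(leaf_nodes[a], leaf_nodes[b])
            assert mrca(tree, [a, b]) is expected
            assert index.mrca(leaf_nodes[a], leaf_nodes[b]) is expected

    def test_idempotent_under_descendant_growth(self):
        tree = random_tree(30, "yule", seed=4)
        labels = [l.label for l in tree.traverse_leaves()][:4]
        anc = mrca(tree, labels)
        # adding a leaf that descends from the current mrca leaves it unchanged
        stack = [anc]
        below = None
        while stack:
            n = stack.pop()
            if n.is_leaf():
                below = n.label
                break
            stack.extend(n.children)
        assert mrca(tree, labels + [below]) is anc


class TestTreeness:
    def test_star_tree_is_zero(self):
        assert treeness(read_tree_newick("(A:1,B:2,C:3)R;")) == 0.0

    def test_hand_example(self):
        tree = read_tree_newick("((A:1,B:3)X:2,C:6)R;")
        assert treeness(tree) == pytest.approx(2 / 12)

    def test_zero_total_length_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            treeness(read_tree_newick("((A,B)X,C)R;"))

    @pytest.mark.parametrize("tree", random_trees(9, 60, seed0=2),
                             ids=lambda t: f"n{t.num_nodes()[0]}")
    def test_bounds_and_complement_identity(self, tree):
        value = treeness(tree)
        assert 0.0 <= value <= 1.0
        total = sum(n.edge_length or 0 for n in tree.traverse_preorder())
        leaf_total = sum(n.edge_length or 0 for n in tree.traverse_leaves())
        assert value + leaf_total / total == pytest.approx(1.0, abs=1e-12)


class TestGamma:
    def test_three_leaf_worked_example(self):
        # branching depths 0 and 0.5, height 1: g2 = g3 = 0.5, T = 2.5
        tree = read_tree_newick("((A:0.5,B:0.5):0.5,C:1);")
        comp = gamma_computation(tree)
        assert comp.n == 3
        assert comp.intervals == pytest.approx([0.5, 0.5])
        assert comp.weighted_total == pytest.approx(2.5)
        expected = (1 * (2 * 0.5) - 1.25) / (2.5 * math.sqrt(1 / 12))
        assert comp.gamma == pytest.approx(expected, abs=1e-12)
        assert comp.gamma == pytest.approx(-0.34641016, abs=1e-7)

    def test_balanced_intervals_give_zero(self):
        # with n=4: choose g2,g3,g4 so the running sums average to T/2.
        # g2=g3=g4=g gives cumsums 2g,5g; mean 3.5g; T=9g, T/2=4.5g -> not 0.
        # instead solve: g2=1, g3=1/3 (so 2*g2 = 2, 2+1 = 3, mean 2.5),
        # pick g4 with T = 5: T = 2 + 1 + 4*g4 = 5 -> g4 = 0.5
        heights = {"g2": 1.0, "g3": 1 / 3, "g4": 0.5}
        d2 = heights["g2"]
        d3 = d2 + heights["g3"]
        h = d3 + heights["g4"]
        nwk = (f"(((A:{heights['g4']},B:{heights['g4']}):{heights['g3']}"
               f",C:{heights['g4'] + heights['g3']}):{heights['g2']}"
               f",D:{h});")
        tree = read_tree_newick(nwk)
        assert gamma_statistic(tree) == pytest.approx(0.0, abs=1e-12)

    def test_non_ultrametric_rejected_with_deviation(self):
        tree = read_tree_newick("((A:1,B:2)X:1,C:2)R;")
        with pytest.raises(NotUltrametricError) as err:
            gamma_statistic(tree)
        assert err.value.max_deviation == pytest.approx(1.0)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            gamma_statistic(read_tree_newick("(A:1,B:1);"))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_oracle(self, seed):
        model = "coalescent" if seed % 2 else "yule"
        tree = random_tree(5 + seed * 3, model, seed=seed)
        assert gamma_statistic(tree) == \
            pytest.approx(gamma_oracle(tree), abs=1e-9)

    def test_yule_null_distribution(self):
        # under pure birth, gamma is asymptotically standard normal
        values = [gamma_statistic(random_tree(50, "yule", seed=s))
                  for s in range(500)]
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert abs(mean) < 0.15
        assert 0.75 < var < 1.25


class TestMinLeafDistances:
    def test_leaves_are_zero_and_hand_values(self):
        tree = read_tree_newick("((A:1,B:3)X:1,C:5)R;")
        values = {n.label: v for n, v in min_leaf_distances(tree).items()}
        assert values["A"] == values["B"] == values["C"] == 0.0
        assert values["X"] == pytest.approx(1.0)
        assert values["R"] == pytest.approx(2.0)

    @pytest.mark.parametrize("tree", random_trees(8, 70, seed0=40),
                             ids=lambda t: f"n{t.num_nodes()[0]}")
    def test_root_value_matches_full_path_oracle(self, tree):
        values = min_leaf_distances(tree)
        expected = min(leaf_depth_walk(l) for l in tree.traverse_leaves())
        assert values[tree.root] == pytest.approx(expected, abs=1e-9)


class TestChildOrderInvariance:
    @pytest.mark.parametrize("seed", range(4))
    def test_statistics_unchanged_by_permutation(self, seed):
        tree = random_tree(25, "coalescent", seed=seed)
        mirror = tree.copy()
        for node in mirror.traverse_preorder():
            node.children.reverse()
        assert height(mirror) == pytest.approx(height(tree))
        assert treeness(mirror) == pytest.approx(treeness(tree))
        assert gamma_statistic(mirror) == pytest.approx(gamma_statistic(tree))
        m1, m2 = distance_matrix(tree), distance_matrix(mirror)
        for a, b in itertools.islice(
                itertools.combinations(m1.labels, 2), 100):
            assert m1[a, b] == pytest.approx(m2[a, b])
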
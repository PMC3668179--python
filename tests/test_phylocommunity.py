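import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from skbio.diversity.beta import unweighted_unifrac as skbio_unifrac

from arisakit.phylocommunity import (
    fitch_changes,
    jackknife_support,
    lineage_specific,
    p_test,
    pcoa,
    tree_clades,
    unifrac_matrix,
    unifrac_pair,
    unifrac_significance,
    upgma,
)

from conftest import caterpillar_tree, random_bifurcating_tree


def unifrac_oracle(tree, A, B):
    """Brute force: shear, collapse, classify each branch by its leaf set."""
    A, B = set(A), set(B)
    t = tree.copy().shear(sorted(A | B))
    t.prune()
    while len(t.children) == 1:  # drop branches above the restricted MRCA
        t = t.children[0]
        t.parent = None
    total = unique = 0.0
    for node in t.traverse(include_self=False):
        leaves = {x.name for x in node.tips()} if not node.is_tip() else {node.name}
        length = node.length or 0.0
        total += length
        in_a, in_b = leaves & A, leaves & B
        if (in_a and not in_b) or (in_b and not in_a):
            unique += length
    if total == 0:
        raise ValueError("no restricted branch length")
    return unique / total


def sankoff_changes(tree, labels):
    """DP oracle: minimum label changes with unit substitution cost."""
    states = sorted(set(labels.values()))
    big = 10**9

    def cost(node):
        if node.is_tip():
            return {s: (0 if labels[node.name] == s else big) for s in states}
        child = [cost(c) for c in node.children]
        return {
            s: sum(min(cc[t] + (s != t) for t in states) for cc in child)
            for s in states
        }

    return min(cost(tree).values())


QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


class TestUniFrac:
    def test_identical_assemblages_zero(self):
        tree = TreeNode.read([QUARTET])
        assert unifrac_pair(tree, {"A", "B"}, {"A", "B"}) == 0.0

    def test_perfect_segregation_one(self):
        tree = TreeNode.read([QUARTET])
        assert unifrac_pair(tree, {"A", "B"}, {"C", "D"}) == 1.0

    def test_interleaved_two_thirds(self):
        tree = TreeNode.read([QUARTET])
        assert unifrac_pair(tree, {"A", "C"}, {"B", "D"}) == pytest.approx(4 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        tree = random_bifurcating_tree(rng, 7)
        a, b = {"L0", "L2", "L5"}, {"L1", "L3"}
        assert unifrac_pair(tree, a, b) == pytest.approx(unifrac_pair(tree, b, a))

    def test_matches_oracle_on_all_small_trees(self):
        """Randomised exhaustive check against the brute-force oracle, n <= 8."""
        rng = np.random.default_rng(2024)
        for rep in range(150):
            n = int(rng.integers(2, 9))
            tree = random_bifurcating_tree(rng, n)
            leaves = [f"L{i}" for i in range(n)]
            a = {x for x in leaves if rng.random() < 0.5}
            b = {x for x in leaves if rng.random() < 0.5}
            if not a or not b or (len(a | b) < 2):
                continue
            try:
                expect = unifrac_oracle(tree, a, b)
            except ValueError:
                continue
            assert unifrac_pair(tree, a, b) == pytest.approx(expect, abs=1e-12)

    def test_matches_skbio_for_covering_partitions(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            tree = random_bifurcating_tree(rng, n)
            leaves = [f"L{i}" for i in range(n)]
            mask = rng.random(n) < 0.5
            if mask.all() or not mask.any():
                continue
            a = {x for x, m in zip(leaves, mask) if m}
            b = set(leaves) - a
            ref = skbio_unifrac(
                [int(x in a) for x in leaves],
                [int(x in b) for x in leaves],
                taxa=leaves,
                tree=tree,
            )
            assert unifrac_pair(tree, a, b) == pytest.approx(float(ref), abs=1e-12)

    def test_matrix_equals_pairwise_recomputation(self):
        rng = np.random.default_rng(7)
        tree = random_bifurcating_tree(rng, 8)
        envs = {
            "e1": {"L0", "L1", "L2"},
            "e2": {"L2", "L3", "L4"},
            "e3": {"L5", "L6", "L7"},
        }
        dm = unifrac_matrix(tree, envs)
        for i in envs:
            for j in envs:
                if i < j:
                    assert dm.loc[i, j] == pytest.approx(
                        unifrac_oracle(tree, envs[i], envs[j]), abs=1e-12
                    )
        assert np.allclose(dm, dm.T) and np.all(np.diag(dm) == 0)


class TestSignificance:
    def test_segregated_minimum_p(self):
        # two fully segregated 15-leaf clades: U_obs is maximal and the
        # chance a label shuffle re-attains it is ~1e-8, so p hits the
        # (1+0)/(1+100) floor
        left = ",".join(f"A{i}:1" for i in range(15))
        right = ",".join(f"B{i}:1" for i in range(15))
        tree = TreeNode.read([f"(({left}):2,({right}):2);"])
        env = {f"A{i}": "x" for i in range(15)}
        env.update({f"B{i}": "y" for i in range(15)})
        p = unifrac_significance(tree, env, n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        tree = random_bifurcating_tree(rng, 10)
        env = {f"L{i}": ("x" if i % 2 else "y") for i in range(10)}
        p1 = unifrac_significance(tree, env, n_perm=50, seed=123)
        p2 = unifrac_significance(tree, env, n_perm=50, seed=123)
        assert p1 == p2

    def test_p_in_unit_interval_with_correction(self):
        rng = np.random.default_rng(11)
        tree = random_bifurcating_tree(rng, 8)
        env = {f"L{i}": ("x" if i < 4 else "y") for i in range(8)}
        p = unifrac_significance(tree, env, n_perm=20, seed=1)
        assert 0 < p <= 1


class TestPTest:
    def test_two_clade_segregation_one_change(self):
        tree = TreeNode.read([QUARTET])
        env = {"A": "x", "B": "x", "C": "y", "D": "y"}
        assert fitch_changes(tree, env) == 1

    def test_caterpillar_alternating_oracle_value(self):
        tree = TreeNode.read(["(((A:1,B:1):1,C:1):1,D:1);"])
        env = {"A": "X", "B": "Y", "C": "X", "D": "Y"}
        assert fitch_changes(tree, env) == 2
        assert sankoff_changes(tree, env) == 2

    def test_fitch_equals_sankoff_on_small_trees(self):
        """Hartigan parsimony equals the Sankoff DP oracle, trees <= 10 leaves."""
        rng = np.random.default_rng(404)
        for rep in range(120):
            n = int(rng.integers(3, 11))
            tree = random_bifurcating_tree(rng, n)
            k = int(rng.integers(2, 4))
            labels = {f"L{i}": f"s{int(rng.integers(k))}" for i in range(n)}
            assert fitch_changes(tree, labels) == sankoff_changes(tree, labels)

    def test_clustered_labels_give_small_p(self):
        rng = np.random.default_rng(21)
        tree = caterpillar_tree(20)
        env = {f"L{i}": ("x" if i < 10 else "y") for i in range(20)}
        p, changes = p_test(tree, env, n_perm=100, seed=3)
        assert changes == 1
        assert p <= 0.05

    def test_seeded_determinism(self):
        tree = caterpillar_tree(8)
        env = {f"L{i}": ("x" if i % 2 else "y") for i in range(8)}
        assert p_test(tree, env, seed=5) == p_test(tree, env, seed=5)


class TestLineageSpecific:
    def test_pure_clade_flagged_small_p(self):
        # a clade of 6 adult-only leaves against a balanced 12-leaf rest
        pure = ",".join(f"A{i}:1" for i in range(1, 7))
        mixed = ",".join(f"M{i}:1" for i in range(1, 13))
        tree = TreeNode.read([f"(({pure}):1,({mixed}):1);"])
        env = {f"A{i}": "adult" for i in range(1, 7)}
        env.update({f"M{i}": ("adult" if i <= 6 else "chick") for i in range(1, 13)})
        out = lineage_specific(tree, env, min_descendants=4)
        pure_leaves = ",".join(sorted(f"A{i}" for i in range(1, 7)))
        pure_row = out[out["clade_leaves"] == pure_leaves].iloc[0]
        assert pure_row["p_value"] < 0.1
        assert pure_row["n_chick_inside"] == 0 and pure_row["n_adult_inside"] == 6

    def test_balanced_node_p_one(self):
        tree = TreeNode.read(
            ["((A1:1,C1:1,A2:1,C2:1):1,(A3:1,C3:1,A4:1,C4:1):1);"]
        )
        env = {f"A{i}": "adult" for i in range(1, 5)}
        env.update({f"C{i}": "chick" for i in range(1, 5)})
        out = lineage_specific(tree, env, min_descendants=4)
        assert (out["p_value"] == 1.0).all()

    def test_min_descendants_larger_than_tree(self):
        tree = TreeNode.read([QUARTET])
        env = {"A": "x", "B": "x", "C": "y", "D": "y"}
        out = lineage_specific(tree, env, min_descendants=10)
        assert out.empty


class TestPCoA:
    def test_two_points(self):
        D = pd.DataFrame([[0, 2.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(D)
        assert res.proportion_explained == pytest.approx([100.0])
        assert sorted(res.coordinates["PC1"]) == pytest.approx([-1.0, 1.0])

    def test_three_equidistant_points_fifty_fifty(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(D)
        assert res.proportion_explained == pytest.approx([50.0, 50.0])

    def test_zero_matrix_empty(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = pcoa(D)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(8)
        X = rng.random((6, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = [f"e{i}" for i in range(6)]
        res = pcoa(pd.DataFrame(D, index=labels, columns=labels))
        C = res.coordinates.to_numpy()
        D2 = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_non_symmetric_rejected(self):
        D = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)


class TestUPGMA:
    def test_first_merge_closed_form(self):
        D = pd.DataFrame(
            [[0, 1.0, 2.0], [1.0, 0, 2.0], [2.0, 2.0, 0]],
            index=list("123"), columns=list("123"),
        )
        tree = upgma(D)
        pair = tree.lca(["1", "2"])
        assert tree.find("1").distance(tree.find("2")) == pytest.approx(1.0)
        assert not pair.is_root()

    def test_ultrametric_input_reproduced(self):
        # distances from a known ultrametric tree come back exactly
        D = pd.DataFrame(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = upgma(D)
        for i in "abcd":
            for j in "abcd":
                if i != j:
                    assert tree.find(i).distance(tree.find(j)) == pytest.approx(D.loc[i, j])

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            X = rng.random((6, 4))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            labels = [f"e{i}" for i in range(6)]
            tree = upgma(pd.DataFrame(D, index=labels, columns=labels))
            Z = linkage(squareform(D), "average")
            coph = squareform(cophenet(Z))
            ours = np.array(
                [
                    [0 if i == j else tree.find(labels[i]).distance(tree.find(labels[j])) for j in range(6)]
                    for i in range(6)
                ]
            )
            assert np.allclose(ours, coph, atol=1e-10)


class TestJackknife:
    def _two_group_setting(self):
        tree = TreeNode.read(
            ["((a1:0.1,a2:0.1,a3:0.1,a4:0.1,a5:0.1,a6:0.1,a7:0.1,a8:0.1):2.0,"
             "(b1:0.1,b2:0.1,b3:0.1,b4:0.1,b5:0.1,b6:0.1,b7:0.1,b8:0.1):2.0);"]
        )
        envs = {
            "A1": {"a1", "a2", "a3", "a4", "a5", "a6"},
            "A2": {"a3", "a4", "a5", "a6", "a7", "a8"},
            "B1": {"b1", "b2", "b3", "b4", "b5", "b6"},
            "B2": {"b3", "b4", "b5", "b6", "b7", "b8"},
        }
        return tree, envs

    def test_strong_signal_top_split_supported(self):
        tree, envs = self._two_group_setting()
        ref, support = jackknife_support(tree, envs, keep=5, n_perm=100, seed=0)
        assert support[frozenset({"A1", "A2"})] >= 0.95 or support[frozenset({"B1", "B2"})] >= 0.95

    def test_keep_everything_all_supports_one(self):
        tree, envs = self._two_group_setting()
        _, support = jackknife_support(tree, envs, keep=50, n_perm=10, seed=1)
        assert all(v == 1.0 for v in support.values())

    def test_seeded_determinism(self):
        tree, envs = self._two_group_setting()
        _, s1 = jackknife_support(tree, envs, keep=4, n_perm=30, seed=9)
        _, s2 = jackknife_support(tree, envs, keep=4, n_perm=30, seed=9)
        assert s1 == s2

    def test_drop_policy_removes_small_environments(self):
        tree, envs = self._two_group_setting()
        envs["tiny"] = {"a1"}
        ref, support = jackknife_support(
            tree, envs, keep=5, n_perm=10, seed=2, small_env_policy="drop"
        )
        assert "tiny" not in {t.name for t in ref.tips()}
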
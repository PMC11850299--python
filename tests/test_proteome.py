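"""Similarity matrix, UPGMA, leaf order, clusters, and group classes.

The hand-worked three-leaf example used throughout:
D(A,B) = 0.2, D(A,C) = 0.6, D(B,C) = 0.4 under average linkage merges
(A,B) at ultrametric height 0.1, then joins C at height 0.25
(= ((0.6 + 0.4) / 2) / 2).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from locusplot import proteome

D3 = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.4], [0.6, 0.4, 0.0]])


def brute_force_upgma_cophenetic(D):
    """Independent oracle: recompute average linkage from scratch each
    merge, tracking cluster member sets; cophenetic distance between two
    leaves is the average-linkage distance at which their clusters merge."""
    n = len(D)
    clusters = [frozenset([i]) for i in range(n)]
    C = np.zeros((n, n))

    def avg_dist(a, b):
        return float(np.mean([[D[i, j] for j in b] for i in a]))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = avg_dist(clusters[x], clusters[y])
                if best is None or d < best[0] - 1e-15:
                    best = (d, x, y)
        d, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                C[i, j] = C[j, i] = d
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return C


class TestSimilarity:
    def test_identical_and_disjoint_sets(self):
        m = proteome.similarity_matrix(
            {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"z"}}
        )
        iA, iB, iC = (m.locus_ids.index(k) for k in "ABC")
        assert m.S[iA, iB] == 1.0 and m.D[iA, iB] == 0.0
        assert m.S[iA, iC] == 0.0

    def test_mean_directional_formula(self):
        """Gi = {a,b,c,d}, Gj = {a,b}: S = (2/4 + 2/2)/2 = 0.75."""
        m = proteome.similarity_matrix(
            {"i": {"a", "b", "c", "d"}, "j": {"a", "b"}}
        )
        assert m.S[0, 1] == pytest.approx(0.75)
        mj = proteome.similarity_matrix(
            {"i": {"a", "b", "c", "d"}, "j": {"a", "b"}}, formula="jaccard"
        )
        assert mj.S[0, 1] == pytest.approx(0.5)

    def test_matrix_properties_random_inputs(self, rng):
        """S symmetric, unit diagonal, in [0,1]; D = 1 - S; identical
        proteomes at distance 0; disjoint at similarity 0."""
        pool = [f"g{i}" for i in range(30)]
        for _ in range(50):
            n = int(rng.integers(1, 13))
            sets = {
                f"L{k}": set(
                    rng.choice(pool, size=int(rng.integers(0, 12)), replace=False)
                )
                for k in range(n)
            }
            m = proteome.similarity_matrix(sets)
            assert np.allclose(m.S, m.S.T)
            assert np.allclose(np.diag(m.S), 1.0)
            assert (m.S >= 0).all() and (m.S <= 1).all()
            offdiag = ~np.eye(n, dtype=bool)
            assert np.allclose(m.D[offdiag], (1.0 - m.S)[offdiag])
            assert np.allclose(np.diag(m.D), 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.sets(st.integers(0, 10), max_size=8), min_size=1, max_size=6
        )
    )
    def test_similarity_invariants_property(self, sets_list):
        """For arbitrary group sets: S symmetric, unit diagonal, [0,1],
        D + S = 1 off-diagonal, and the merge heights are non-decreasing."""
        sets = {f"L{i}": {f"g{x}" for x in s} for i, s in enumerate(sets_list)}
        m = proteome.similarity_matrix(sets)
        n = len(sets)
        assert np.allclose(m.S, m.S.T)
        assert np.allclose(np.diag(m.S), 1.0)
        assert (m.S >= 0).all() and (m.S <= 1).all()
        assert np.allclose(m.D + m.S, 1.0)
        tree = proteome.upgma(m.D, m.locus_ids)
        heights = []

        def walk(node):
            if not node.is_leaf:
                heights.append(node.height)
                walk(node.left)
                walk(node.right)

        walk(tree)
        for h in heights:
            assert h <= tree.height + 1e-12

    def test_empty_proteome_does_not_perturb_others(self):
        sets = {"A": {"x", "y"}, "B": {"x"}}
        base = proteome.similarity_matrix(sets).S[0, 1]
        with_empty = proteome.similarity_matrix({**sets, "E": set()})
        assert with_empty.S[0, 1] == base
        assert with_empty.S[0, 2] == 0.0


class TestUpgma:
    def test_two_leaf_merge_height(self):
        tree = proteome.upgma(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        assert tree.height == pytest.approx(0.2)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        tree = proteome.upgma(D3, ["A", "B", "C"])
        assert tree.height == pytest.approx(0.25)
        inner = tree.left if not tree.left.is_leaf else tree.right
        assert inner.height == pytest.approx(0.1)
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_single_leaf(self):
        tree = proteome.upgma(np.zeros((1, 1)), ["A"])
        assert tree.is_leaf and tree.name == "A"

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            proteome.upgma(np.array([[0, 1], [2, 0]]), ["A", "B"])

    def test_relabelling_equivariance(self):
        """The same distances under leaf relabelling give isomorphic trees."""
        t1 = proteome.upgma(D3, ["A", "B", "C"])
        perm = [2, 0, 1]  # C, A, B
        Dp = D3[np.ix_(perm, perm)]
        t2 = proteome.upgma(Dp, ["C", "A", "B"])
        c1 = proteome.cophenetic_matrix(t1, ["A", "B", "C"])
        c2 = proteome.cophenetic_matrix(t2, ["A", "B", "C"])
        assert np.allclose(c1, c2)

    @pytest.mark.parametrize("trial", range(20))
    def test_brute_force_oracle_equivalence(self, trial):
        """Cophenetic matrices match a from-scratch average-linkage oracle
        (and scipy's implementation) on random matrices, n <= 6."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 7))
        M = rng.random((n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"L{i}" for i in range(n)]
        tree = proteome.upgma(D, labels)
        C = proteome.cophenetic_matrix(tree, labels)
        assert np.allclose(C, brute_force_upgma_cophenetic(D), atol=1e-9)
        Z = average(squareform(D, checks=False))
        assert np.allclose(C, squareform(cophenet(Z)), atol=1e-9)

    def test_cophenetic_is_ultrametric(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"L{i}" for i in range(n)]
            C = proteome.cophenetic_matrix(proteome.upgma(D, labels), labels)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        if len({i, j, k}) == 3:
                            assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-12


class TestLeafOrderAndClusters:
    def test_leaf_order_of_hand_example(self):
        tree = proteome.upgma(D3, ["A", "B", "C"])
        assert proteome.leaf_order(tree) == ["A", "B", "C"]

    def test_order_override_wins(self):
        tree = proteome.upgma(D3, ["A", "B", "C"])
        assert proteome.leaf_order(tree, override=["C", "A", "B"]) == ["C", "A", "B"]

    def test_cut_thresholds(self):
        tree = proteome.upgma(D3, ["A", "B", "C"])
        # cophenetic distances: d(A,B)=0.2, d(*,C)=0.5
        assert proteome.cut_clusters(tree, 0.3) == {"A": "C1", "B": "C1", "C": "C2"}
        assert proteome.cut_clusters(tree, 0.75) == {"A": "C1", "B": "C1", "C": "C1"}

    def test_degenerate_cuts(self):
        n = 4
        labels = [f"L{i}" for i in range(n)]
        zero = proteome.upgma(np.zeros((n, n)), labels)
        assert set(proteome.cut_clusters(zero, 0.75).values()) == {"C1"}
        ones = 1.0 - np.eye(n)
        far = proteome.upgma(ones, labels)
        assert len(set(proteome.cut_clusters(far, 0.75).values())) == n


class TestClassify:
    def test_presence_fraction_classes(self):
        members = {"C1": ["L1", "L2", "L3", "L4"]}
        sets = {
            "L1": {"core", "half", "uniq"},
            "L2": {"core", "half"},
            "L3": {"core"},
            "L4": {"core"},
        }
        classes = proteome.classify_groups(members, sets)["C1"]
        assert classes["core"] == (1.0, "conserved")
        assert classes["half"] == (0.5, "intermediate")
        assert classes["uniq"] == (0.25, "variable")

    def test_singleton_cluster_all_conserved(self):
        classes = proteome.classify_groups({"C1": ["L1"]}, {"L1": {"a", "b"}})
        assert all(cls == "conserved" for _f, cls in classes["C1"].values())

    def test_partition_of_groups(self, rng):
        members = {"C1": [f"L{i}" for i in range(5)]}
        pool = [f"g{i}" for i in range(15)]
        sets = {
            lid: set(rng.choice(pool, size=int(rng.integers(1, 10)), replace=False))
            for lid in members["C1"]
        }
        classes = proteome.classify_groups(members, sets)["C1"]
        all_groups = set().union(*sets.values())
        assert set(classes) == all_groups
        counts = {"conserved": 0, "intermediate": 0, "variable": 0}
        for _f, cls in classes.values():
            counts[cls] += 1
        assert sum(counts.values()) == len(all_groups)


class TestExports:
    def test_newick_of_hand_example(self):
        tree = proteome.upgma(D3, ["A", "B", "C"])
        assert proteome.to_newick(tree) == "((A:0.1,B:0.1):0.15,C:0.25);"

    def test_newick_single_leaf(self):
        tree = proteome.upgma(np.zeros((1, 1)), ["A"])
        assert proteome.to_newick(tree) == "A;"

    def test_newick_parses_with_dendropy(self):
        import dendropy

        tree = proteome.upgma(D3, ["A", "B", "C"])
        t = dendropy.Tree.get(data=proteome.to_newick(tree), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"A", "B", "C"}

    def test_similarity_tsv_round_trip(self, tmp_path):
        m = proteome.similarity_matrix({"A": {"x"}, "B": {"x", "y"}})
        path = tmp_path / "sim.tsv"
        proteome.write_similarity_tsv(m, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3
        assert lines[1].split("\t")[2] == lines[2].split("\t")[1]
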
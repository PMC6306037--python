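"""Distances, neighbor joining, bootstrap and tanglegram congruence."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix as SkDM
from skbio.tree import nj as skbio_nj

from myxopan import (
    DistanceMatrix,
    bootstrap_support,
    distance_from_identity,
    distance_from_profile,
    entanglement_null_test,
    k2p_distance,
    k2p_pair,
    neighbor_joining,
    random_tree,
    robinson_foulds,
    simulate_predation,
    tanglegram,
    tree_distances,
)
from myxopan.delimit import IdentityMatrix
from myxopan.trees import count_crossings


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p_pair("ACGTACGT", "ACGTACGT") == 0.0

    def test_worked_example_p10_q05(self):
        # 100 sites, 10 transitions, 5 transversions -> 0.1702
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        assert k2p_pair(s1, s2) == pytest.approx(0.1702, abs=1e-4)

    def test_ambiguous_sites_excluded_pairwise(self):
        # the only difference sits at an N site -> distance 0
        assert k2p_pair("ACGTN", "ACGTA") == 0.0
        assert k2p_pair("ACG-A", "ACGTA") == 0.0

    def test_saturated_pair_reported_undefined(self):
        dm = k2p_distance({"a": "ACGT" * 5, "b": "CAAC" * 5, "c": "ACGT" * 5})
        # a-c identical; whether a-b is defined depends on saturation
        assert dm[("a", "c")] == 0.0

    def test_undefined_when_log_argument_nonpositive(self):
        # all transversions: Q = 1 -> 1-2Q < 0
        d = k2p_pair("AAAA", "CCCC")
        assert np.isnan(d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        v = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(labels, v))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_matrix_roundtrip_exact(self, balanced_tree):
        dm = tree_distances(balanced_tree)
        rebuilt = neighbor_joining(dm)
        dm2 = tree_distances(rebuilt)
        a = dm.to_frame().loc[sorted(dm.labels), sorted(dm.labels)]
        b = dm2.to_frame().loc[sorted(dm.labels), sorted(dm.labels)]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)
        assert robinson_foulds(rebuilt, balanced_tree) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recover_topology(self, seed):
        t = random_tree([f"L{i}" for i in range(4 + seed % 7)], seed=seed)
        rebuilt = neighbor_joining(tree_distances(t))
        assert robinson_foulds(rebuilt, t) == 0.0
        # and the path metric is reproduced exactly (additivity)
        a = tree_distances(t).to_frame()
        b = tree_distances(rebuilt).to_frame().loc[a.index, a.columns]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_skbio_nj_topology(self, seed):
        """Independent cross-check against scikit-bio's NJ."""
        t = random_tree([f"L{i}" for i in range(8)], seed=100 + seed)
        dm = tree_distances(t)
        mine = neighbor_joining(dm)
        theirs = skbio_nj(SkDM(dm.values, dm.labels))
        assert robinson_foulds(mine, theirs) == 0.0

    def test_two_taxa_trivial_tree_with_warning(self):
        with pytest.warns(UserWarning):
            tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]])))
        assert {t.name for t in tree.tips()} == {"a", "b"}


class TestDistanceConstructors:
    def test_identity_transform(self):
        frame = pd.DataFrame(
            [[100.0, 82.0], [82.0, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        d = distance_from_identity(IdentityMatrix(frame))
        assert d[("a", "b")] == pytest.approx(0.18)
        assert d[("a", "a")] == 0.0

    def test_identity_transform_is_monotone(self):
        rng = np.random.default_rng(1)
        vals = np.sort(rng.uniform(75, 99, size=5))
        dists = [(100.0 - v) / 100.0 for v in vals]
        assert all(x > y for x, y in zip(dists, dists[1:]))

    def test_jaccard_on_binary_profiles(self):
        rows = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"], dtype=bool)
        d = distance_from_profile(rows, metric="jaccard")
        assert d[("a", "b")] == pytest.approx(2 / 3)

    def test_identical_rows_distance_zero(self):
        rows = pd.DataFrame([[3.0, 1.0, 4.0]] * 2, index=["a", "b"])
        with pytest.warns(UserWarning):  # zero-variance columns dropped
            d = distance_from_profile(rows)
        assert d[("a", "b")] == 0.0

    def test_column_permutation_leaves_distances_unchanged(self):
        rng = np.random.default_rng(2)
        rows = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        d1 = distance_from_profile(rows)
        d2 = distance_from_profile(rows.iloc[:, ::-1])
        assert np.allclose(d1.values, d2.values)


class TestBootstrap:
    def make_alignment(self):
        """Two clades separated by 16 fixed transitions over 200 sites."""
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=200))
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}

        def mutate(s, positions):
            arr = list(s)
            for i in positions:
                arr[i] = transitions[arr[i]]
            return "".join(arr)

        fixed = rng.choice(200, size=16, replace=False)
        right = mutate(base, fixed)
        free = [i for i in range(200) if i not in set(fixed)]
        return {
            "a1": base,
            "a2": mutate(base, free[:2]),
            "a3": mutate(base, free[2:4]),
            "b1": right,
            "b2": mutate(right, free[4:6]),
            "b3": mutate(right, free[6:8]),
        }

    def test_separating_edge_gets_high_support(self):
        tree = bootstrap_support(self.make_alignment(), replicates=100, seed=5)
        supports = [float(n.name) for n in tree.non_tips() if n.name]
        assert supports, "no internal support values attached"
        assert max(supports) >= 95.0
        assert all(0.0 <= s <= 100.0 for s in supports)

    def test_seeded_determinism(self):
        aln = self.make_alignment()
        t1 = bootstrap_support(aln, replicates=30, seed=7)
        t2 = bootstrap_support(aln, replicates=30, seed=7)
        assert str(t1) == str(t2)


class TestTanglegram:
    def test_identical_trees_zero_everything(self, balanced_tree):
        res = tanglegram(balanced_tree, balanced_tree.copy(), seed=0)
        assert res.crossings == 0
        assert res.entanglement == 0.0
        assert res.rf_distance == 0.0

    def test_mirrored_leaf_order_untangles_completely(self, balanced_tree):
        from myxopan.io import read_newick

        mirrored = read_newick("(((H:1,G:1):1,(F:1,E:1):1):1,((D:1,C:1):1,(B:1,A:1):1):1);")
        res = tanglegram(balanced_tree, mirrored, seed=0)
        assert res.crossings == 0
        assert res.rf_distance == 0.0

    def test_crossing_count_is_inversion_count(self):
        assert count_crossings(list("abcd"), list("abcd")) == 0
        assert count_crossings(list("abcd"), list("dcba")) == 6
        assert count_crossings(list("abc"), list("bac")) == 1

    def test_optimization_never_increases_crossings(self, balanced_tree):
        rng = np.random.default_rng(3)
        for seed in range(5):
            t2 = random_tree(list("ABCDEFGH"), seed=seed)
            before = count_crossings(
                [t.name for t in balanced_tree.tips()], [t.name for t in t2.tips()]
            )
            res = tanglegram(balanced_tree, t2, seed=seed)
            assert res.crossings <= before

    def test_leaf_set_mismatch_rejected(self, balanced_tree):
        other = random_tree(list("ABCXYZEF"), seed=0)
        with pytest.raises(ValueError, match="differ"):
            tanglegram(balanced_tree, other)

    def test_congruent_predation_tree_matches_source(self, balanced_tree):
        pred, _ = simulate_predation(balanced_tree, n_prey=60, congruence=1.0, seed=2)
        ptree = neighbor_joining(distance_from_profile(pred))
        assert robinson_foulds(ptree, balanced_tree) == 0.0

    def test_incongruent_predation_is_null_like(self, balanced_tree):
        """congruence=0 predation trees are indistinguishable from the
        random-permutation null."""
        pred, _ = simulate_predation(balanced_tree, n_prey=30, congruence=0.0, seed=4)
        ptree = neighbor_joining(distance_from_profile(pred))
        res = entanglement_null_test(balanced_tree, ptree, permutations=49, seed=0)
        assert res["p_value"] > 0.05
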
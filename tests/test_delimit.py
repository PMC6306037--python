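"""Tiered ANI/dDDH genomospecies delimitation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from myxopan import (
    IdentityMatrix,
    cluster_at_threshold,
    compare_groupings,
    ddh_groups,
    delimit,
    nine_species_preset,
    rand_index,
    simulate_identity_matrix,
)


def block_matrix(blocks, within, between, labels=None):
    """Planted block identity matrix (no noise)."""
    n = sum(blocks)
    labels = labels or [f"s{i}" for i in range(n)]
    v = np.full((n, n), between, dtype=float)
    start = 0
    for b in blocks:
        v[start:start + b, start:start + b] = within
        start += b
    np.fill_diagonal(v, 100.0)
    return IdentityMatrix(pd.DataFrame(v, index=labels, columns=labels))


class TestClusterAtThreshold:
    def test_single_cluster_when_all_similar(self):
        m = block_matrix([4], within=96, between=96)
        assert cluster_at_threshold(m, 95) == [[f"s{i}" for i in range(4)]]

    def test_blocks_recovered_as_connected_components(self):
        m = block_matrix([3, 2, 4], within=96, between=85)
        clusters = cluster_at_threshold(m, 95)
        assert [len(c) for c in clusters] == [3, 2, 4]

    def test_threshold_100_gives_singletons(self):
        m = block_matrix([1, 1, 1], within=99, between=90)
        assert cluster_at_threshold(m, 100) == [["s0"], ["s1"], ["s2"]]

    def test_nestedness_across_thresholds(self):
        """Clusters at a higher threshold refine those at a lower one."""
        m, _ = simulate_identity_matrix([3, 2, 2], seed=11)
        coarse = cluster_at_threshold(m, 85)
        fine = cluster_at_threshold(m, 95)
        coarse_sets = [set(c) for c in coarse]
        for cl in fine:
            assert any(set(cl) <= cs for cs in coarse_sets)


class TestDelimit:
    def test_nine_species_preset_gives_9_to_11_species(self):
        ani, truth = nine_species_preset(seed=0)
        g = delimit(ani)
        assert g.species_count_range == (9, 11)
        assert g.genus_ok
        assert g.conflicts == []
        assert truth.n_species() == 9
        assert truth.n_subspecies_groups() == 11
        # exactly two species consist of two subspecies each
        multi = [subs for subs in g.subspecies if len(subs) > 1]
        assert len(multi) == 2
        assert all(len(subs) == 2 for subs in multi)

    def test_subspecies_band_pair_is_one_species_two_subspecies(self):
        v = pd.DataFrame([[100.0, 93.5], [93.5, 100.0]], index=["a", "b"], columns=["a", "b"])
        g = delimit(IdentityMatrix(v))
        assert g.species_count_range == (1, 2)
        assert g.species == [["a", "b"]]
        assert g.subspecies == [[["a"], ["b"]]]

    def test_pair_below_genus_floor_flags_genus(self):
        m = block_matrix([2, 2], within=96, between=70)
        g = delimit(m)
        assert not g.genus_ok

    def test_gap_values_reported_as_conflicts(self):
        v = pd.DataFrame([[100.0, 92.5], [92.5, 100.0]], index=["a", "b"], columns=["a", "b"])
        g = delimit(IdentityMatrix(v))
        assert any(c["reason"] == "gap_92_93" for c in g.conflicts)

    def test_requires_ani_kind(self):
        m = block_matrix([2], within=96, between=96)
        m.kind = "dDDH"
        with pytest.raises(ValueError, match="ANI"):
            delimit(m)

    def test_invariant_under_relabeling(self):
        ani, _ = nine_species_preset(seed=5)
        perm = list(reversed(ani.labels))
        shuffled = IdentityMatrix(ani.df.loc[perm, perm])
        a = delimit(ani)
        b = delimit(shuffled)
        assert a.species_count_range == b.species_count_range
        assert sorted(map(sorted, a.species)) == sorted(map(sorted, b.species))

    def test_single_group_returns_one_species(self):
        m, _ = simulate_identity_matrix([4], seed=2)
        assert delimit(m).species_count_range == (1, 1)

    def test_two_planted_species_recovered(self):
        m, _ = simulate_identity_matrix(
            [2, 2], within=(96, 99), between_species=(85, 90), seed=3
        )
        g = delimit(m)
        assert g.species_count_range == (2, 2)


class TestDdhGroups:
    def test_one_group_at_every_threshold_when_all_high(self):
        m = block_matrix([3], within=80, between=80)
        m.kind = "dDDH"
        groups = ddh_groups(m)
        assert all(len(g) == 1 for g in groups.values())

    def test_blocks_at_50_singletons_at_70(self):
        m = block_matrix([2, 3], within=60, between=20)
        m.kind = "dDDH"
        groups = ddh_groups(m)
        assert [len(c) for c in groups[50.0]] == [2, 3]
        assert all(len(c) == 1 for c in groups[70.0])

    def test_strict_70_can_split_a_50_group_into_three(self):
        """A >50% chain whose links drop below 70% splits at the
        stricter cut-off — the known ANI/dDDH disagreement pattern."""
        v = np.array([
            [100.0, 70.5, 55.0],
            [70.5, 100.0, 55.0],
            [55.0, 55.0, 100.0],
        ])
        labels = list("abc")
        m = IdentityMatrix(pd.DataFrame(v, index=labels, columns=labels), kind="dDDH")
        groups = ddh_groups(m)
        assert len(groups[50.0]) == 1
        assert len(groups[70.0]) == 2  # strict >70 keeps only the 70.5 edge

    def test_threshold_strictness(self):
        v = pd.DataFrame([[100.0, 50.0], [50.0, 100.0]], index=["a", "b"], columns=["a", "b"])
        m = IdentityMatrix(v, kind="dDDH")
        assert len(ddh_groups(m)[50.0]) == 2  # exactly 50 is NOT >50


class TestCompareGroupings:
    def test_identical_partitions_give_rand_1(self):
        p = [["a", "b"], ["c"]]
        r = compare_groupings(p, [["a", "b"], ["c"]])
        assert r["rand_index"] == 1.0
        assert r["differing_genomes"] == []

    def test_rand_matches_pair_enumeration(self):
        a = [["w"], ["x"], ["y"], ["z"]]
        b = [["w", "x", "y", "z"]]
        # all 6 pairs disagree -> Rand 0
        assert compare_groupings(a, b)["rand_index"] == 0.0

    def test_rand_matches_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(0)
        labels = [f"g{i}" for i in range(12)]
        for _ in range(20):
            la = rng.integers(0, 4, size=12)
            lb = rng.integers(0, 3, size=12)
            part_a = [[labels[i] for i in range(12) if la[i] == k] for k in range(4)]
            part_a = [p for p in part_a if p]
            part_b = [[labels[i] for i in range(12) if lb[i] == k] for k in range(3)]
            part_b = [p for p in part_b if p]
            assert rand_index(part_a, part_b) == pytest.approx(rand_score(la, lb))

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_groupings([["a"]], [["b"]])

    def test_ani_and_ddh_tiers_concord_on_planted_data(self):
        """dDDH >50 mirrors the ANI >=95 tier (11 groups); dDDH >30
        mirrors the merged species tier (9 groups)."""
        ani, _ = nine_species_preset(seed=7)
        ddh, _ = nine_species_preset(
            seed=8, kind="dDDH",
            between_genus=(10.0, 18.0), between_species=(20.0, 28.0),
            subspecies_band=(32.0, 45.0), within=(55.0, 80.0),
        )
        groups = ddh_groups(ddh)
        tight = cluster_at_threshold(ani, 95)
        assert compare_groupings(tight, groups[50.0])["rand_index"] == 1.0
        species = delimit(ani).species
        assert compare_groupings(species, groups[30.0])["rand_index"] == 1.0
        assert len(groups[50.0]) == 11
        assert len(groups[30.0]) == 9
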
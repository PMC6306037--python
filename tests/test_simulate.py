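"""The synthetic-data generators: determinism, degenerate cases and
parameter recovery by the downstream analysis stages."""

import numpy as np
import pytest

from myxopan import (
    assembly_stats,
    delimit,
    fit_heaps,
    gc_content,
    n50_l50,
    nine_species_preset,
    partition,
    random_tree,
    rarefy,
    simulate_annotations,
    simulate_contigs,
    simulate_identity_matrix,
    simulate_pangenome,
    simulate_predation,
)


class TestSimulatePangenome:
    def test_same_seed_identical_matrices(self):
        a, _ = simulate_pangenome(n_genomes=8, core_size=50, kappa=300, gamma=0.5, seed=42)
        b, _ = simulate_pangenome(n_genomes=8, core_size=50, kappa=300, gamma=0.5, seed=42)
        assert a == b

    def test_core_genes_present_everywhere(self):
        m, truth = simulate_pangenome(n_genomes=6, core_size=30, kappa=200, gamma=0.5, seed=1)
        core_rows = m.df.loc[[i for i in m.orthogroups if i.startswith("core_")]]
        assert core_rows.all().all()
        assert truth.core_size == 30

    def test_near_zero_accessory_rate_gives_pure_core(self):
        m, _ = simulate_pangenome(
            n_genomes=6, core_size=40, kappa=1e-9, gamma=0.5, retention=1.0, seed=2
        )
        part = partition(m)
        assert part.tier_counts["hard_core"] == m.pan_size == 40

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_pangenome(n_genomes=1)
        with pytest.raises(ValueError):
            simulate_pangenome(gamma=1.2)
        with pytest.raises(ValueError):
            simulate_pangenome(kappa=-1)
        with pytest.raises(ValueError):
            simulate_pangenome(retention=0.0)

    def test_heaps_recovery_small_scale(self):
        """Fitted gamma tracks the generating gamma (reduced-size run;
        the full-scale recovery lives in the acceptance suite)."""
        gammas = []
        for seed in range(20):
            m, _ = simulate_pangenome(n_genomes=24, seed=seed)
            fit = fit_heaps(rarefy(m, permutations=30, seed=seed))
            gammas.append(fit.gamma)
        assert abs(np.mean(gammas) - 0.55) <= 0.05


class TestSimulateIdentity:
    def test_two_planted_species_recovered_exactly(self):
        m, truth = simulate_identity_matrix(
            [2, 2], within=(96, 99), between_species=(85, 90), seed=0
        )
        assert delimit(m).species_count_range == (2, 2)
        assert truth.n_species() == 2

    def test_single_group_all_within(self):
        m, _ = simulate_identity_matrix([4], within=(96, 99), seed=1)
        off = m.values()[~np.eye(4, dtype=bool)]
        assert ((off >= 95.5) & (off <= 99.5)).all()
        assert delimit(m).species_count_range == (1, 1)

    def test_nine_species_tiers(self):
        m, truth = nine_species_preset(seed=3)
        g = delimit(m)
        assert g.species_count_range == (9, 11)
        assert truth.n_species() == 9

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_identity_matrix(
                [2, 2], subspecies_splits={0: [1, 1]},
                within=(95.5, 99), subspecies_band=(93, 95.4), noise_sd=0.2, seed=0,
            )

    def test_determinism(self):
        a, _ = simulate_identity_matrix([3, 2], seed=9)
        b, _ = simulate_identity_matrix([3, 2], seed=9)
        assert a.df.equals(b.df)


class TestSimulateAnnotations:
    def _partition(self, seed=0):
        m, _ = simulate_pangenome(n_genomes=12, core_size=800, kappa=2500, gamma=0.55, seed=seed)
        return partition(m)

    def test_no_planted_folds_no_calls(self):
        from myxopan import cog_profile, compare_profiles

        part = self._partition()
        ann, _ = simulate_annotations(
            part, base_profile={"E": 10, "J": 10, "Q": 5, "S": 50}, seed=0
        )
        result = compare_profiles(
            cog_profile(ann, part.accessory_orthogroups),
            cog_profile(ann, part.core_orthogroups),
        )
        assert result.enriched == [] and result.impoverished == []

    def test_planted_category_must_exist(self):
        part = self._partition()
        with pytest.raises(ValueError, match="absent"):
            simulate_annotations(part, base_profile={"E": 10}, planted={"Q": 1.5}, seed=0)

    def test_determinism(self):
        part = self._partition()
        kwargs = dict(base_profile={"E": 10, "Q": 5, "S": 50}, planted={"Q": 1.0}, seed=4)
        a, _ = simulate_annotations(part, **kwargs)
        b, _ = simulate_annotations(part, **kwargs)
        assert a == b


class TestSimulatePredation:
    def test_all_diameters_non_negative(self):
        tree = random_tree([f"s{i}" for i in range(10)], seed=0)
        for seed in range(5):
            pred, _ = simulate_predation(tree, n_prey=8, congruence=0.5, seed=seed)
            assert (pred.to_numpy() >= 0).all()

    def test_shape_and_labels(self):
        tree = random_tree(list("abcde"), seed=1)
        pred, truth = simulate_predation(tree, n_prey=7, congruence=0.3, seed=2)
        assert pred.shape == (5, 7)
        assert set(pred.index) == set("abcde")
        assert truth.predation_congruence == 0.3

    def test_determinism(self):
        tree = random_tree(list("abcde"), seed=1)
        a, _ = simulate_predation(tree, n_prey=4, congruence=0.8, seed=3)
        b, _ = simulate_predation(tree, n_prey=4, congruence=0.8, seed=3)
        assert a.equals(b)

    def test_congruence_validation(self):
        tree = random_tree(list("abc"), seed=0)
        with pytest.raises(ValueError):
            simulate_predation(tree, congruence=1.5, seed=0)


class TestSimulateContigs:
    def test_lengths_sum_to_genome_size(self):
        recs = simulate_contigs(50_000, 12, seed=0)
        assert sum(len(r.seq) for r in recs) == 50_000
        assert len(recs) == 12

    def test_single_contig_n50_equals_genome_size(self):
        recs = simulate_contigs(5_000, 1, seed=1)
        assert n50_l50([len(r.seq) for r in recs]) == (5_000, 1)

    def test_headers_carry_length_and_coverage(self):
        recs = simulate_contigs(10_000, 4, coverage_range=(10, 20), seed=2)
        for r in recs:
            assert f"_length_{len(r.seq)}_cov_" in r.id

    def test_requested_gc_realized_within_one_point(self):
        recs = simulate_contigs(200_000, 10, gc=0.699, seed=3)
        assert gc_content(recs) == pytest.approx(69.9, abs=1.0)

    def test_determinism_and_validation(self):
        a = simulate_contigs(10_000, 3, seed=5)
        b = simulate_contigs(10_000, 3, seed=5)
        assert all(str(x.seq) == str(y.seq) and x.id == y.id for x, y in zip(a, b))
        with pytest.raises(ValueError):
            simulate_contigs(5, 10, seed=0)
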
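import numpy as np
import pandas as pd
import pytest

from lanthnet.corrnet import build_count_matrix, spearman_rho
from lanthnet.synth import (
    SimConfig,
    calibrate_effect,
    empirical_effect_rho,
    simulate_genomic,
    simulate_sequences,
    simulate_transcriptome,
)


class TestConfigValidation:
    def test_effect_out_of_range(self):
        with pytest.raises(ValueError):
            SimConfig(effect=1.5)

    def test_negative_sizes(self):
        with pytest.raises(ValueError):
            SimConfig(n_genera=-1)

    def test_short_consensus(self):
        with pytest.raises(ValueError):
            SimConfig(seq_length=10)


class TestGenomicSimulation:
    CFG = SimConfig(
        n_genera=3, genomes_per_genus=30, n_planted_pairs=3,
        n_background_pre=5, n_background_prot=5, effect=0.8, seed=13,
    )

    def test_same_seed_reproduces_identical_tables(self):
        a = simulate_genomic(self.CFG)
        b = simulate_genomic(self.CFG)
        pd.testing.assert_frame_equal(a.pre_counts, b.pre_counts)
        pd.testing.assert_frame_equal(a.prot_counts, b.prot_counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.assignments == b.assignments

    def test_different_seed_differs(self):
        import dataclasses

        a = simulate_genomic(self.CFG)
        b = simulate_genomic(dataclasses.replace(self.CFG, seed=14))
        assert not a.pre_counts.equals(b.pre_counts)

    def test_assignments_consistent_with_count_matrices(self):
        sim = simulate_genomic(self.CFG)
        pre = build_count_matrix(
            [a for a in sim.assignments if a.group_kind == "precursor"],
            sim.member_to_genome,
            [g.genome_id for g in sim.genomes],
        )
        pd.testing.assert_frame_equal(pre, sim.pre_counts, check_names=False)

    def test_truth_lists_one_row_per_partner(self):
        sim = simulate_genomic(self.CFG)
        assert len(sim.truth) == 3  # one co-expressed partner per unit, no decoys
        assert sim.truth["coexpressed"].all()

    def test_effect_one_duplicates_counts(self):
        cfg = SimConfig(
            n_genera=1, genomes_per_genus=40, n_planted_pairs=1,
            n_background_pre=0, n_background_prot=0, effect=1.0, seed=5,
        )
        sim = simulate_genomic(cfg)
        assert (sim.pre_counts["Pre_1"] == sim.prot_counts["Prot_1"]).all()
        rho = spearman_rho(sim.pre_counts["Pre_1"], sim.prot_counts["Prot_1"])
        assert rho == pytest.approx(1.0)

    def test_effect_zero_has_no_population_correlation(self):
        assert empirical_effect_rho(0.0, n=10_000, seed=3) == pytest.approx(0.0, abs=0.03)

    def test_population_rho_monotone_in_effect(self):
        rhos = [
            np.mean([empirical_effect_rho(e, n=4000, seed=s) for s in range(10)])
            for e in (0.0, 0.3, 0.6, 1.0)
        ]
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_calibration_hits_target(self):
        effect = calibrate_effect(0.7, n=100_000, seed=2)
        assert empirical_effect_rho(effect, n=100_000, seed=99) == pytest.approx(0.7, abs=0.02)


class TestSequenceSimulation:
    def test_three_families_recovered_and_identity_bounds(self):
        from lanthnet.grouping import pairwise_identity

        sim = simulate_sequences(SimConfig(seq_families=3, seq_members_per_family=6, seed=8))
        members = sorted(sim.proteases)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                ident = pairwise_identity(sim.proteases[a], sim.proteases[b])
                if sim.families[a] == sim.families[b]:
                    assert ident >= 0.8
                else:
                    assert ident <= 0.5  # construction bound plus mutation slack

    def test_single_family_clusters_to_one_group(self):
        from lanthnet.grouping import cluster_members

        sim = simulate_sequences(SimConfig(seq_families=1, seq_members_per_family=8, seed=3))
        assert len(cluster_members(sim.proteases, 0.45)) == 1

    def test_zero_mutation_rate_gives_identical_members(self):
        sim = simulate_sequences(
            SimConfig(seq_families=2, seq_members_per_family=5, seq_mutation_rate=0.0, seed=4)
        )
        by_family: dict[str, set[str]] = {}
        for member, fam in sim.families.items():
            if member in sim.proteases:
                by_family.setdefault(fam, set()).add(sim.proteases[member])
        assert all(len(seqs) == 1 for seqs in by_family.values())

    def test_determinism(self):
        cfg = SimConfig(seed=6)
        assert simulate_sequences(cfg).proteases == simulate_sequences(cfg).proteases


class TestTranscriptomeSimulation:
    CFG = SimConfig(
        n_genera=2, genomes_per_genus=40, n_planted_pairs=1,
        n_coexpressed_partners=1, n_decoy_partners=1,
        n_background_pre=3, n_background_prot=3,
        effect=0.9, n_samples=20, n_strains=3, seed=19,
    )

    def _group_rho(self, sim, table, pre, prot):
        from lanthnet.coexpress import group_tpm, tpm_matrix

        grouped = group_tpm(tpm_matrix(table), sim.assignments)
        return spearman_rho(grouped[pre].to_numpy(), grouped[prot].to_numpy())

    def test_coexpressed_pair_strongly_rank_correlated(self):
        sim = simulate_genomic(self.CFG)
        tx = simulate_transcriptome(self.CFG, sim)
        true_pair = sim.truth[sim.truth.coexpressed].iloc[0]
        rhos = [
            self._group_rho(sim, table, true_pair.pre_group, true_pair.prot_group)
            for table in tx.strain_tables.values()
        ]
        assert all(r > 0.4 for r in rhos)

    def test_decoy_pair_uncorrelated_on_average(self):
        from lanthnet.coexpress import group_tpm, tpm_matrix

        rhos = []
        for seed in range(8):
            import dataclasses

            cfg = dataclasses.replace(self.CFG, seed=seed)
            sim = simulate_genomic(cfg)
            tx = simulate_transcriptome(cfg, sim)
            decoy = sim.truth[~sim.truth.coexpressed].iloc[0]
            for table in tx.strain_tables.values():
                grouped = group_tpm(tpm_matrix(table), sim.assignments)
                if decoy.prot_group in grouped.columns:
                    rhos.append(
                        spearman_rho(
                            grouped[decoy.pre_group].to_numpy(),
                            grouped[decoy.prot_group].to_numpy(),
                        )
                    )
        assert len(rhos) >= 8
        assert abs(np.mean(rhos)) < 0.25

    def test_determinism(self):
        sim = simulate_genomic(self.CFG)
        a = simulate_transcriptome(self.CFG, sim)
        b = simulate_transcriptome(self.CFG, sim)
        for strain in a.strain_tables:
            pd.testing.assert_frame_equal(a.strain_tables[strain], b.strain_tables[strain])

    def test_too_few_samples_is_an_error(self):
        import dataclasses

        cfg = dataclasses.replace(self.CFG, n_samples=2)
        sim = simulate_genomic(self.CFG)
        with pytest.raises(ValueError, match="n_samples"):
            simulate_transcriptome(cfg, sim)
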
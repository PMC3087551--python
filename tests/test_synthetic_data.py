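"""Species trees, family histories, sequence evolution, genome assembly."""

import numpy as np
import pytest

from lpxevo import synthetic_data as sd

from oracles import expected_leaf_copies, mc_mean_leaf_copies


class TestSpeciesTree:
    def test_smallest_case_has_three_leaves(self):
        t = sd.simulate_species_tree(3, seed=1)
        assert len(t.leaves()) == 3
        assert len(t.nodes) == 5  # 2n - 1 nodes

    def test_node_count_follows_binary_formula(self):
        t = sd.simulate_species_tree(61, seed=7)
        assert len(t.leaves()) == 61
        assert len(t.nodes) == 2 * 61 - 1

    def test_deterministic_newick(self):
        a = sd.simulate_species_tree(15, seed=3).to_newick()
        b = sd.simulate_species_tree(15, seed=3).to_newick()
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            sd.simulate_species_tree(2, seed=0)

    def test_branch_lengths_nonnegative_and_labels_unique(self):
        t = sd.simulate_species_tree(30, seed=9)
        assert all(n.length >= 0 for n in t.nodes.values())
        labels = t.leaf_labels()
        assert len(set(labels)) == len(labels)


class TestFamilyHistories:
    def test_no_events_means_one_copy_everywhere(self, species_tree20):
        hists, truth = sd.simulate_family_histories(species_tree20, 9, 0.0, 0.0, seed=1)
        for h in hists:
            assert all(v == [1] for v in h.leaf_copies.values())
            assert len(h.leaf_copies) == 20

    def test_forced_duplication_doubles_descendants(self, species_tree20):
        t = species_tree20
        branch = t.nodes[t.root].children[0]
        hists, _ = sd.simulate_family_histories(
            t, 1, 0.0, 0.0, seed=2, forced_duplications={"fam1": [branch]}
        )
        below = {t.nodes[l].label for l in t.leaves(branch)}
        for genome, copies in hists[0].leaf_copies.items():
            assert len(copies) == (2 if genome in below else 1)

    def test_unknown_gain_branch_rejected(self, species_tree20):
        with pytest.raises(ValueError, match="gain branch"):
            sd.simulate_family_histories(
                species_tree20, 1, 0.0, 0.0, gain_branches={"fam1": "nope"}, seed=0
            )

    def test_negative_rates_rejected(self, species_tree20):
        with pytest.raises(ValueError, match="rates"):
            sd.simulate_family_histories(species_tree20, 1, -0.1, 0.0, seed=0)

    def test_mean_copy_number_matches_branching_process(self, species_tree20):
        """Mean leaf copy number across many families sits within Monte-
        Carlo error of an independent re-simulation and the closed form."""
        dup, loss = 0.05, 0.05
        hists, _ = sd.simulate_family_histories(species_tree20, 200, dup, loss, seed=3)
        means = [
            sum(len(v) for v in h.leaf_copies.values()) / 20 for h in hists
        ]
        observed = float(np.mean(means))
        mc = mc_mean_leaf_copies(species_tree20, dup, loss, n_reps=10_000, seed=4)
        closed = expected_leaf_copies(species_tree20, dup, loss)
        se = float(np.std(means, ddof=1) / np.sqrt(len(means)))
        assert abs(observed - mc) <= 4 * se
        assert abs(mc - closed) < 0.05

    def test_zero_count_lineages_have_no_descendants(self, species_tree20):
        hists, truth = sd.simulate_family_histories(species_tree20, 30, 0.05, 0.15, seed=5)
        for h in hists:
            for genome, copies in h.leaf_copies.items():
                assert len(copies) == truth.presence[genome][h.family]
                assert all(c > 0 for c in copies)


class TestEvolve:
    def test_zero_branch_lengths_preserve_root(self, species_tree20):
        t = species_tree20.copy()
        for n in t.nodes.values():
            n.length = 0.0
        hists, _ = sd.simulate_family_histories(t, 1, 0.0, 0.0, seed=1)
        rng = np.random.default_rng(0)
        root = sd.random_protein(100, rng)
        seqs = sd.evolve_sequences(t, hists, {"fam1": root}, seed=2)
        for recs in seqs.values():
            assert all(s == root for _, _, s in recs)

    def test_motif_columns_never_substituted(self):
        tree = sd.simulate_species_tree(10, seed=6)
        hists, _ = sd.simulate_family_histories(tree, 1, 0.0, 0.0, seed=6)
        rng = np.random.default_rng(6)
        root, frozen, _ = sd.plant_motif(150, ["D", "GD", "GNRE", "H", "GHAH"], (5, 20), rng)
        seqs = sd.evolve_sequences(tree, hists, {"fam1": root},
                                   frozen_masks={"fam1": frozen}, seed=7)
        idx = np.flatnonzero(frozen)
        for recs in seqs.values():
            for _, _, s in recs:
                assert all(s[i] == root[i] for i in idx)

    def test_substitution_fraction_matches_closed_form(self):
        """Branch length 1.0 under equal rates: changed-site fraction within
        3 standard errors of the Markov closed form."""
        model = sd.SubstitutionModel()
        p = model.p_change(1.0)
        rng = np.random.default_rng(8)
        root = sd.random_protein(5000, rng)
        evolved = model.evolve(root, 1.0, rng)
        changed = sum(a != b for a, b in zip(root, evolved)) / len(root)
        se = np.sqrt(p * (1 - p) / len(root))
        assert abs(changed - p) <= 3 * se

    def test_empty_root_sequence_rejected(self, species_tree20):
        hists, _ = sd.simulate_family_histories(species_tree20, 1, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="empty root"):
            sd.evolve_sequences(species_tree20, hists, {"fam1": ""}, seed=0)

    def test_copy_conservation(self, species_tree20):
        """Emitted records per family equal the summed leaf copy counts."""
        hists, _ = sd.simulate_family_histories(species_tree20, 5, 0.08, 0.05, seed=9)
        rng = np.random.default_rng(9)
        roots = {h.family: sd.random_protein(60, rng) for h in hists}
        seqs = sd.evolve_sequences(species_tree20, hists, roots, seed=10)
        for h in hists:
            emitted = sum(
                1 for recs in seqs.values() for _, fam, _ in recs if fam == h.family
            )
            assert emitted == sum(len(v) for v in h.leaf_copies.values())


class TestAssemble:
    def make_sequences(self, n_genomes=3, fams=("lpxC", "fabZ", "other")):
        rng = np.random.default_rng(11)
        return {
            f"G{i:02d}": [
                (f"{f}|G{i:02d}|c1", f, sd.random_protein(80, rng)) for f in fams
            ]
            for i in range(1, n_genomes + 1)
        }

    def test_no_fusion_keeps_gene_count(self):
        seqs = self.make_sequences()
        recs, fasta = sd.assemble_genomes(seqs, fusion_prob=0.0, seed=1)
        assert len(recs) == sum(len(v) for v in seqs.values())
        assert len(fasta) == len(recs)

    def test_zero_gap_cluster_is_adjacent(self):
        seqs = self.make_sequences()
        truth = sd.TruthLog()
        recs, _ = sd.assemble_genomes(
            seqs, cluster_spec=["lpxC", "fabZ"], cluster_gap=0, seed=2, truth=truth
        )
        for genome, cluster_ids in truth.clusters.items():
            order = [r.gene_id for r in recs if r.genome == genome]
            i = order.index(cluster_ids[0])
            assert order[i : i + len(cluster_ids)] == cluster_ids

    def test_forced_fusion_in_every_genome(self):
        seqs = self.make_sequences(n_genomes=50)
        truth = sd.TruthLog()
        recs, fasta = sd.assemble_genomes(
            seqs, fusion_pair=("lpxC", "fabZ"), fusion_prob=1.0, seed=3, truth=truth
        )
        assert len(truth.fusions) == 50
        for f in truth.fusions:
            assert fasta[f["gene_id"]]  # fused record exists
        # fused genes shrink the per-genome record count by one
        per_genome = {}
        for r in recs:
            per_genome[r.genome] = per_genome.get(r.genome, 0) + 1
        assert all(v == 2 for v in per_genome.values())

    def test_coordinates_non_overlapping_half_open(self):
        seqs = self.make_sequences()
        recs, _ = sd.assemble_genomes(seqs, seed=4)
        by_contig = {}
        for r in recs:
            by_contig.setdefault((r.genome, r.contig), []).append(r)
        for recs_c in by_contig.values():
            recs_c.sort(key=lambda r: r.start)
            for a, b in zip(recs_c, recs_c[1:]):
                assert a.end <= b.start
            assert all(r.end > r.start >= 0 for r in recs_c)

    def test_byte_identical_under_seed(self):
        seqs = self.make_sequences()
        r1, f1 = sd.assemble_genomes(seqs, cluster_spec=["lpxC"], seed=5)
        r2, f2 = sd.assemble_genomes(seqs, cluster_spec=["lpxC"], seed=5)
        assert sd.gene_table_to_tsv(r1) == sd.gene_table_to_tsv(r2)
        assert f1 == f2

    def test_gene_table_roundtrip(self):
        seqs = self.make_sequences()
        recs, _ = sd.assemble_genomes(seqs, seed=6)
        text = sd.gene_table_to_tsv(recs)
        assert sd.gene_table_from_tsv(text) == recs
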
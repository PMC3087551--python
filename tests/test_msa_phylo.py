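"""Alignment, distances, NJ, bootstrap, likelihood, concatenation."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from lpxevo import msa_phylo as mp
from lpxevo import synthetic_data as sd
from lpxevo.trees import Tree


def additive_matrix(tree):
    labels = tree.leaf_labels()
    l2n = tree.label_to_leaf()

    def dist(a, b):
        na, nb = l2n[a], l2n[b]
        pa = [na] + list(tree.ancestors(na))
        pb = [nb] + list(tree.ancestors(nb))
        common = set(pa) & set(pb)
        d = 0.0
        for n in pa:
            if n in common:
                break
            d += tree.nodes[n].length
        for n in pb:
            if n in common:
                break
            d += tree.nodes[n].length
        return d

    D = np.array([[dist(a, b) for b in labels] for a in labels])
    return mp.DistanceMatrix(labels, D)


class TestAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = mp.progressive_align([("a", "ACDEF"), ("b", "ACDEF"), ("c", "ACDEF")])
        assert aln.seqs == ["ACDEF"] * 3

    def test_two_sequences_match_global_dp_oracle(self, scheme):
        """Pairwise case achieves the Needleman-Wunsch optimum computed by
        Biopython's global aligner with identical scoring."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.5
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = sd.random_protein(int(rng.integers(10, 60)), rng)
            b = sd.random_protein(int(rng.integers(10, 60)), rng)
            aln = mp.progressive_align([("a", a), ("b", b)], scheme)
            # score my alignment columns under the oracle's scoring
            score = 0.0
            in_gap = {0: False, 1: False}
            m = substitution_matrices.load("BLOSUM62")
            for ca, cb in zip(*aln.seqs):
                if ca != "-" and cb != "-":
                    score += m[ca][cb]
                    in_gap = {0: False, 1: False}
                else:
                    k = 0 if ca == "-" else 1
                    score += -0.5 - (10.0 if not in_gap[k] else 0.0)
                    in_gap[k] = True
                    in_gap[1 - k] = False
            assert score == pytest.approx(aligner.score(a, b))

    def test_planted_motif_columns_stay_aligned(self):
        """>= 90% of invariant motif residues end up in shared columns."""
        rng = np.random.default_rng(4)
        tree = sd.simulate_species_tree(10, seed=4)
        hists, _ = sd.simulate_family_histories(tree, 1, 0.0, 0.0, seed=4)
        root, frozen, starts = sd.plant_motif(200, ["D", "GD", "GNRE", "H", "GHAH"], (8, 25), rng)
        seqs = sd.evolve_sequences(tree, hists, {"fam1": root},
                                   frozen_masks={"fam1": frozen}, seed=5)
        members = [(gid, s) for recs in seqs.values() for gid, _f, s in recs]
        aln = mp.progressive_align(members)
        motif_positions = np.flatnonzero(frozen)

        def col_of(row: str, pos: int) -> int:
            """Alignment column of the (pos+1)-th residue of a row."""
            seen = -1
            for c, ch in enumerate(row):
                if ch != "-":
                    seen += 1
                    if seen == pos:
                        return c
            raise AssertionError("position beyond row")

        # simulation never indels, so residue `pos` is homologous across rows
        shared = sum(
            1
            for pos in motif_positions
            if len({col_of(s, pos) for s in aln.seqs}) == 1
        )
        assert shared >= 0.9 * len(motif_positions)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            mp.progressive_align([("a", "ACD")])


class TestDistances:
    def test_identical_rows_zero(self):
        aln = mp.Alignment(["a", "b"], ["ACDEF", "ACDEF"])
        assert mp.distances(aln).D[0, 1] == 0.0

    def test_p_distance_definition(self):
        a = "A" * 95 + "C" * 5
        b = "A" * 95 + "D" * 5
        aln = mp.Alignment(["a", "b"], [a, b])
        assert mp.distances(aln).D[0, 1] == pytest.approx(0.05)

    def test_poisson_correction_closed_form(self):
        a = "A" * 95 + "C" * 5
        b = "A" * 95 + "D" * 5
        aln = mp.Alignment(["a", "b"], [a, b])
        assert mp.distances(aln, "poisson").D[0, 1] == pytest.approx(-math.log(0.95))

    def test_no_shared_columns_rejected(self):
        aln = mp.Alignment(["a", "b"], ["A--", "--C"])
        with pytest.raises(ValueError):
            mp.distances(aln)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = mp.neighbor_joining(mp.DistanceMatrix(["a", "b", "c"], D))
        lens = {t.nodes[l].label: t.nodes[l].length for l in t.leaves()}
        assert lens["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lens["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lens["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_exact_recovery_on_additive_matrices(self):
        """100 random 6-8 taxon trees are recovered exactly from their
        path-length matrices (topology and branch lengths)."""
        recovered = 0
        for i in range(100):
            n = 6 + i % 3
            tree = sd.simulate_species_tree(n, seed=1000 + i)
            dm = additive_matrix(tree)
            nj = mp.neighbor_joining(dm)
            if nj.bipartitions() == tree.bipartitions():
                # branch lengths: compare leaf-to-leaf path lengths
                dm2 = additive_matrix(nj)
                order = [dm2.ids.index(x) for x in dm.ids]
                if np.allclose(dm2.D[np.ix_(order, order)], dm.D, atol=1e-9):
                    recovered += 1
        assert recovered == 100

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            mp.DistanceMatrix(["a", "b", "c"], D)


class TestBootstrap:
    def test_unanimous_columns_give_full_support(self):
        # one split supported by every column: AB | CD
        rows = ["AAAA", "AAAA", "CCCC", "CCCC"]
        aln = mp.Alignment(list("abcd"), rows)
        t = mp.bootstrap(aln, n_reps=50, seed=0, correction="none")
        sups = [t.nodes[n].support for n in t.preorder()
                if not t.is_leaf(n) and n != t.root and t.nodes[n].support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_zero_reps_leaves_supports_unset(self):
        aln = mp.Alignment(list("abc"), ["AC", "AC", "CC"])
        t = mp.bootstrap(aln, n_reps=0, seed=0, correction="none")
        assert all(t.nodes[n].support is None for n in t.preorder())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACDE"), size=60)) for _ in range(5)]
        aln = mp.Alignment(list("abcde"), rows)
        t1 = mp.bootstrap(aln, 30, seed=3, correction="none")
        t2 = mp.bootstrap(aln, 30, seed=3, correction="none")
        assert t1.to_newick(supports=True) == t2.to_newick(supports=True)

    def test_clean_signal_gives_high_support(self):
        """Long internal branches: true bipartitions nearly always >= 95%."""
        tree = sd.simulate_species_tree(8, seed=99)
        for n in tree.nodes.values():
            n.length = max(n.length, 0.15)  # lengthen internals for signal
        hists, _ = sd.simulate_family_histories(tree, 1, 0.0, 0.0, seed=99)
        rng = np.random.default_rng(99)
        root = sd.random_protein(500, rng)
        seqs = sd.evolve_sequences(tree, hists, {"fam1": root}, seed=100)
        members = [(recs[0][0].split("|")[1], recs[0][2]) for recs in seqs.values()]
        aln = mp.progressive_align(members)
        t = mp.bootstrap(aln, 100, seed=101)
        true_bips = tree.bipartitions()
        got = {
            min(frozenset(t.nodes[l].label or l for l in t.leaves(n)),
                frozenset(t.leaf_labels()) - frozenset(t.nodes[l].label or l for l in t.leaves(n)),
                key=lambda s: (len(s), sorted(s))): t.nodes[n].support
            for n in t.preorder() if not t.is_leaf(n) and n != t.root
        }
        strong = sum(1 for b in true_bips if got.get(b, 0) and got[b] >= 95)
        assert strong >= 0.8 * len(true_bips)


class TestLikelihood:
    def two_leaf_tree(self, t1=0.3, t2=0.2):
        t = Tree()
        t.add_node("r")
        t.add_node("a", "r", t1, label="A")
        t.add_node("b", "r", t2, label="B")
        return t

    def test_two_leaf_closed_form(self):
        t = self.two_leaf_tree()
        aln = mp.Alignment(["A", "B"], ["A", "C"])
        model = mp.PhyloModel()
        P = expm(model.rate_matrix() * 0.5)
        expected = math.log(0.05 * P[0, 1])
        assert mp.loglik(t, aln, model) == pytest.approx(expected, abs=1e-9)

    def test_four_leaf_matches_state_enumeration(self):
        """Pruning equals brute-force summation over internal states."""
        t = Tree()
        t.add_node("r")
        t.add_node("u", "r", 0.1)
        t.add_node("v", "r", 0.2)
        t.add_node("a", "u", 0.3, label="A")
        t.add_node("b", "u", 0.15, label="B")
        t.add_node("c", "v", 0.25, label="C")
        t.add_node("d", "v", 0.4, label="D")
        aln = mp.Alignment(["A", "B", "C", "D"], ["AC", "CC", "DA", "AC"])
        model = mp.PhyloModel()
        Q = model.rate_matrix()
        P = {n: expm(Q * t.nodes[n].length) for n in ("u", "v", "a", "b", "c", "d")}
        code = {ch: i for i, ch in enumerate(mp.ALPHABET)}
        expected = 0.0
        for col in range(2):
            obs = {rid: code[aln.row(rid)[col]] for rid in aln.ids}
            like = 0.0
            for r_state, u_state, v_state in itertools.product(range(20), repeat=3):
                like += (
                    0.05
                    * P["u"][r_state, u_state]
                    * P["v"][r_state, v_state]
                    * P["a"][u_state, obs["A"]]
                    * P["b"][u_state, obs["B"]]
                    * P["c"][v_state, obs["C"]]
                    * P["d"][v_state, obs["D"]]
                )
            expected += math.log(like)
        assert mp.loglik(t, aln, model) == pytest.approx(expected, abs=1e-9)

    def test_large_alpha_converges_to_no_gamma(self):
        t = self.two_leaf_tree()
        aln = mp.Alignment(["A", "B"], ["ACDEF", "ACDWF"])
        flat = mp.loglik(t, aln, mp.PhyloModel())
        gamma = mp.loglik(t, aln, mp.PhyloModel(alpha=1e6, k_categories=4))
        assert gamma == pytest.approx(flat, abs=1e-3)

    def test_invariant_under_rerooting(self):
        tree = sd.simulate_species_tree(6, seed=55)
        hists, _ = sd.simulate_family_histories(tree, 1, 0.0, 0.0, seed=55)
        rng = np.random.default_rng(55)
        seqs = sd.evolve_sequences(tree, hists, {"fam1": sd.random_protein(80, rng)}, seed=56)
        members = [(recs[0][0].split("|")[1], recs[0][2]) for recs in seqs.values()]
        aln = mp.progressive_align(members)
        model = mp.PhyloModel(alpha=0.8)
        base = mp.loglik(tree, aln, model)
        for leaf in list(tree.leaves())[:3]:
            rerooted = tree.reroot_on_edge(leaf)
            assert mp.loglik(rerooted, aln, model) == pytest.approx(base, abs=1e-6)

    def test_leaf_mismatch_rejected(self):
        t = self.two_leaf_tree()
        aln = mp.Alignment(["A", "X"], ["A", "C"])
        with pytest.raises(ValueError):
            mp.loglik(t, aln, mp.PhyloModel())


class TestConcatenate:
    def test_lengths_add_and_missing_gene_becomes_gap_block(self):
        a1 = mp.Alignment(["g1|A|c1", "g1|B|c1"], ["AC", "AC"])
        a2 = mp.Alignment(["g2|A|c1"], ["DEF"])
        genome_of = {"g1|A|c1": "A", "g1|B|c1": "B", "g2|A|c1": "A"}
        cat = mp.concatenate({"g1": a1, "g2": a2}, genome_of)
        assert cat.n_cols == 5
        assert cat.row("B") == "AC---"
        assert cat.col_source == ["g1", "g1", "g2", "g2", "g2"]

    def test_duplicate_copy_resolved_by_score(self):
        a1 = mp.Alignment(["g1|A|c1", "g1|A|c2", "g1|B|c1"], ["AC", "GG", "AC"])
        genome_of = {k: k.split("|")[1] for k in a1.ids}
        scores = {"g1|A|c1": 5.0, "g1|A|c2": 9.0, "g1|B|c1": 1.0}
        cat = mp.concatenate({"g1": a1}, genome_of, scores)
        assert cat.row("A") == "GG"
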
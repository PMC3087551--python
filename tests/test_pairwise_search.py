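"""Local alignment scoring, E-value statistics, and reciprocal best hits."""



import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpxevo import pairwise_search as ps
from lpxevo import synthetic_data as sd

from oracles import brute_local_score

IDENTITY = np.full((21, 21), -1.0)
np.fill_diagonal(IDENTITY, 1.0)
IDENTITY[20, :] = IDENTITY[:, 20] = -1.0


def identity_scheme():
    return ps.ScoringScheme(matrix=IDENTITY, gap_open=9.0, gap_extend=1.0)


class TestSmithWaterman:
    def test_self_alignment_scores_length(self):
        sch = identity_scheme()
        hit = ps.smith_waterman("ACDEFGHIKL", "ACDEFGHIKL", sch)
        assert hit.raw == 10.0
        assert (hit.qstart, hit.qend, hit.tstart, hit.tend) == (0, 10, 0, 10)

    def test_no_positive_pair_gives_zero_and_empty_intervals(self):
        sch = identity_scheme()
        hit = ps.smith_waterman("ACDEF", "GGGGG", sch)
        assert hit.raw == 0.0
        assert (hit.qstart, hit.qend, hit.tstart, hit.tend) == (0, 0, 0, 0)

    def test_illegal_residue_is_named(self):
        with pytest.raises(ValueError, match="B"):
            ps.smith_waterman("ABC", "ACD", identity_scheme())

    def test_x_scored_as_worst_match(self, scheme):
        clean = ps.smith_waterman("ACDEFGHIKL", "ACDEFGHIKL", scheme).raw
        with_x = ps.smith_waterman("ACDEXGHIKL", "ACDEFGHIKL", scheme).raw
        assert with_x < clean

    def test_matches_exhaustive_enumeration(self, scheme):
        """200 random short pairs agree with chain-enumeration brute force."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            la, lb = rng.integers(1, 13, size=2)
            a = rng.integers(0, 20, size=la)
            b = rng.integers(0, 20, size=lb)
            expected = brute_local_score(a, b, scheme.matrix, scheme.gap_open,
                                         scheme.gap_extend)
            got = ps.smith_waterman(
                "".join(ps.ALPHABET[i] for i in a),
                "".join(ps.ALPHABET[i] for i in b),
                scheme,
            ).raw
            assert got == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=ps.ALPHABET, min_size=1, max_size=25),
           st.text(alphabet=ps.ALPHABET, min_size=1, max_size=25))
    def test_score_symmetry(self, a, b):
        sch = identity_scheme()
        assert ps.smith_waterman(a, b, sch).raw == ps.smith_waterman(b, a, sch).raw


class TestEvalue:
    def test_effective_database_length_constant(self):
        assert ps.SearchConfig().effective_db_length == 6_400_000

    def test_monotone_decreasing_in_score(self, scheme):
        cfg = ps.SearchConfig()
        evs = [ps.evalue(s, 320, cfg, scheme) for s in (20, 50, 100, 500)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-50

    def test_proportional_to_database_length(self, scheme):
        e1 = ps.evalue(80, 320, ps.SearchConfig(genome_size=20_000), scheme)
        e2 = ps.evalue(80, 320, ps.SearchConfig(genome_size=40_000), scheme)
        assert e2 == pytest.approx(2 * e1)

    def test_uncalibrated_scheme_rejected(self):
        sch = identity_scheme()
        with pytest.raises(ValueError, match="calibration"):
            ps.evalue(50, 320, ps.SearchConfig(), sch)

    def test_gapped_lambda_below_ungapped(self, scheme):
        assert scheme.lam < ps.ungapped_lambda(scheme)

    def test_shuffle_null_agrees_with_evalue_scale(self, scheme):
        """Exceedance frequency of random-pair scores tracks E/n within 3x."""
        rng = np.random.default_rng(5)
        n, length = 3000, 150
        scores = np.empty(n)
        for i in range(n):
            a = rng.choice(20, size=length, p=scheme.background)
            b = rng.choice(20, size=length, p=scheme.background)
            scores[i] = ps.sw_score(a, b, scheme.matrix, scheme.gap_open,
                                    scheme.gap_extend)
        cfg = ps.SearchConfig()
        # per-trial null probability implied by the E-value formula
        for q in (0.5, 0.9, 0.99):
            s = float(np.quantile(scores, q))
            p_model = ps.evalue(s, length, cfg, scheme) / (
                cfg.effective_db_length * length / (length * length)
            )
            p_obs = float((scores >= s).mean())
            assert p_model / 3 <= p_obs <= p_model * 3


class TestSearchAndRBH:
    def test_query_finds_itself_first(self, scheme):
        rng = np.random.default_rng(1)
        query = sd.random_protein(150, rng)
        proteome = [("self", query)] + [
            (f"d{i}", sd.random_protein(150, rng)) for i in range(10)
        ]
        hits = ps.search_genome(query, proteome, scheme=scheme)
        assert hits and hits[0].target == "self"

    def test_random_proteome_rarely_hits(self, scheme):
        """E <= 0.01 keeps false positives near the calibration expectation."""
        rng = np.random.default_rng(2)
        query = sd.random_protein(150, rng)
        false = 0
        for _ in range(100):
            proteome = [(f"d{i}", sd.random_protein(150, rng)) for i in range(20)]
            false += len(ps.search_genome(query, proteome, scheme=scheme))
        # 100 searches x 20 seqs at per-sequence rate 0.01/20000: expect ~0
        assert false <= 5

    def test_identical_proteomes_are_mutual_best_hits(self, scheme):
        rng = np.random.default_rng(3)
        genes = [(f"fam{i}|ref|c1", sd.random_protein(120, rng)) for i in range(3)]
        twin = [(gid.replace("ref", "twin"), s) for gid, s in genes]
        refs = {f"fam{i}": ("ref", [genes[i][0]]) for i in range(3)}
        asg = ps.reciprocal_best_hits(refs, {"ref": genes, "twin": twin},
                                      scheme=scheme)
        for i in range(3):
            fam = f"fam{i}"
            assert asg[fam]["twin"] == [twin[i][0]]
            assert asg[fam]["ref"] == [genes[i][0]]

    def test_planted_loss_yields_no_assignment(self, scheme):
        rng = np.random.default_rng(4)
        genes = [(f"fam{i}|ref|c1", sd.random_protein(120, rng)) for i in range(2)]
        refs = {f"fam{i}": ("ref", [genes[i][0]]) for i in range(2)}
        other = [("fam0|g2|c1", genes[0][1])]  # genome keeps only fam0
        asg = ps.reciprocal_best_hits(refs, {"ref": genes, "g2": other},
                                      scheme=scheme)
        assert "g2" in asg["fam0"]
        assert "g2" not in asg.get("fam1", {})

    def test_missing_reference_genome_rejected(self, scheme):
        with pytest.raises(ValueError, match="reference genome"):
            ps.reciprocal_best_hits({"f": ("nope", ["x"])}, {"a": [("x", "ACD")]},
                                    scheme=scheme)
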
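import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lpxevo import pairwise_search as ps
from lpxevo import profile_hmm as ph
from lpxevo import synthetic_data as sd


@pytest.fixture(scope="session")
def scheme():
    """BLOSUM62 scheme with the shipped Gumbel calibration."""
    return ps.default_scheme()


@pytest.fixture(scope="session")
def species_tree20():
    return sd.simulate_species_tree(20, seed=42)


@pytest.fixture(scope="session")
def toy_hmm():
    """Three-match-state model from a tiny gapped seed alignment."""
    rows = [("r1", "AC-D"), ("r2", "ACWD"), ("r3", "GCWD"), ("r4", "AC-D")]
    return ph.build_hmm(rows, occupancy_threshold=0.5, pseudocount_weight=0.5)


@pytest.fixture(scope="session")
def calibrated_family_hmm():
    """A realistic family model: 12 sequences evolved from one root."""
    rng = np.random.default_rng(7)
    tree = sd.simulate_species_tree(12, seed=7)
    hists, _ = sd.simulate_family_histories(tree, 1, 0.0, 0.0, seed=7)
    root = sd.random_protein(320, rng)
    seqs = sd.evolve_sequences(tree, hists, {"fam1": root}, seed=8)
    members = [(gid, s) for recs in seqs.values() for gid, _f, s in recs]
    from lpxevo import msa_phylo

    aln = msa_phylo.progressive_align(members)
    hmm = ph.build_hmm(list(zip(aln.ids, aln.seqs)))
    ph.calibrate(hmm, 1000, seed=9)
    return hmm, root, tree
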
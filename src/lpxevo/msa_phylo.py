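"""Multiple alignment, distances, neighbor joining, bootstrap, likelihood.

Tree *search* is by neighbor joining on Poisson-corrected distances; maximum
likelihood enters only as fixed-tree scoring (Felsenstein pruning with an
optional discrete-Gamma rate model), which is the role trees play in this
pipeline — scaffolds for event inference, not the object of study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import expm
from scipy.spatial.distance import squareform
from scipy.stats import gamma as gamma_dist

from ._kernels import nw_fill
from .pairwise_search import ALPHABET, ScoringScheme, default_scheme, encode
from .trees import Tree


@dataclass
class Alignment:
    ids: List[str]
    seqs: List[str]
    col_source: Optional[List[str]] = None  # per-column source gene (concatenations)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row(self, rid: str) -> str:
        return self.seqs[self.ids.index(rid)]

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.seqs))


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------
def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _profile(aln_rows: List[str]) -> np.ndarray:
    """Per-column residue frequency profile (gaps excluded, renormalised)."""
    ncol = len(aln_rows[0])
    prof = np.zeros((ncol, 20))
    for r in aln_rows:
        x = encode(r.replace("-", "A"))  # placeholder; gaps masked below
        for c, ch in enumerate(r):
            if ch != "-":
                prof[c, x[c] if x[c] < 20 else 0] += 1.0
    sums = prof.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return prof / sums


def progressive_align(
    seqs: Sequence[Tuple[str, str]],
    scheme: Optional[ScoringScheme] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Guide-tree progressive alignment.

    K-mer distances feed average-linkage clustering (the guide tree);
    profiles are merged bottom-up by global affine-gap alignment of
    column-frequency profiles under the expected substitution score.
    For two sequences this reduces exactly to pairwise global DP.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    scheme = scheme or default_scheme()
    ids = [i for i, _ in seqs]
    raw = {i: s for i, s in seqs}
    if len(seqs) == 2:
        merged = _merge([raw[ids[0]]], [raw[ids[1]]], scheme, gap_open, gap_extend)
        return Alignment(ids=list(ids), seqs=merged)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(raw[ids[i]], raw[ids[j]])
    Z = hierarchy.average(squareform(D, checks=False))
    groups: Dict[int, List[str]] = {i: [ids[i]] for i in range(n)}
    aligned: Dict[int, List[str]] = {i: [raw[ids[i]]] for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        rows = _merge(aligned[ia], aligned[ib], scheme, gap_open, gap_extend)
        k = n + step
        groups[k] = groups[ia] + groups[ib]
        aligned[k] = rows
    order = groups[n + len(Z) - 1]
    rows = aligned[n + len(Z) - 1]
    # restore input order
    perm = [order.index(i) for i in ids]
    return Alignment(ids=list(ids), seqs=[rows[p] for p in perm])


def _merge(rows_a: List[str], rows_b: List[str], scheme: ScoringScheme,
           gop: float, gext: float) -> List[str]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ scheme.matrix[:20, :20] @ pb.T
    _, layer, ptr = nw_fill(S, gop, gext)
    i, j = pa.shape[0], pb.shape[0]
    path: List[Tuple[bool, bool]] = []
    while i > 0 or j > 0:
        p = ptr[layer, i, j]
        if layer == 0:
            path.append((True, True))
            i, j = i - 1, j - 1
            layer = p - 1
        elif layer == 1:
            path.append((True, False))
            i -= 1
            layer = 0 if p == 1 else 1
        else:
            path.append((False, True))
            j -= 1
            layer = 0 if p == 1 else 2
    path.reverse()
    out = []
    for rows, take_first in ((rows_a, True), (rows_b, False)):
        for r in rows:
            buf, pos = [], 0
            for ta, tb in path:
                take = ta if take_first else tb
                if take:
                    buf.append(r[pos])
                    pos += 1
                else:
                    buf.append("-")
            out.append("".join(buf))
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    ids: List[str]
    D: np.ndarray
    saturated: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("diagonal must be zero")


def distances(aln: Alignment, correction: str = "none") -> DistanceMatrix:
    """p-distances over mutually ungapped columns; optional Poisson correction
    ``-ln(1-p)``.  Pairs with p >= 1 (or no shared columns within a pair) are
    flagged as saturated and capped."""
    if len(aln.ids) < 2:
        raise ValueError("need >= 2 rows")
    n = len(aln.ids)
    mats = np.array([[ord(c) for c in s] for s in aln.seqs], dtype=np.int16)
    gap = mats == ord("-")
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(f"no shared ungapped columns for {aln.ids[i]}, {aln.ids[j]}")
            p = float((mats[i, shared] != mats[j, shared]).sum()) / m
            if correction == "poisson":
                if p >= 1.0 - 1e-12:
                    saturated.append((aln.ids[i], aln.ids[j]))
                    d = -math.log(1.0 / m)  # cap at the resolution of the data
                else:
                    d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=list(aln.ids), D=D, saturated=saturated)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------
def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; deterministic with lexicographic
    tie-breaks; negative branch estimates clamped to zero with the deficit
    moved to the sibling branch.  Returns an unrooted tree (trifurcating
    root)."""
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 taxa")
    D = dm.D.astype(float).copy()
    active = list(range(len(ids)))
    tree = Tree()
    # node ids for active lineages
    node_of: Dict[int, Tuple[str, float]] = {}  # index -> (subtree newick-ish id, pending length)
    subtrees: Dict[int, dict] = {i: {"leaf": ids[i]} for i in range(len(ids))}
    next_idx = len(ids)
    D_full = {(i, i): 0.0 for i in active}
    for i in active:
        for j in active:
            D_full[(i, j)] = D[i, j]

    def d(i: int, j: int) -> float:
        return D_full[(i, j)]

    while len(active) > 3:
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        n = len(active)
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n - 2) * d(i, j) - r[i] - r[j]
                key = (q, _pair_label(subtrees, i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (n - 2))
        lj = d(i, j) - li
        li, lj = _clamp_pair(li, lj)
        new = {"children": [(subtrees[i], li), (subtrees[j], lj)]}
        for k in active:
            if k in (i, j):
                continue
            D_full[(next_idx, k)] = D_full[(k, next_idx)] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        D_full[(next_idx, next_idx)] = 0.0
        subtrees[next_idx] = new
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    root = {"children": [(subtrees[i], max(li, 0.0)), (subtrees[j], max(lj, 0.0)),
                         (subtrees[k], max(lk, 0.0))]}
    _build_tree(tree, root, None, 0.0)
    return tree


def _pair_label(subtrees: Dict[int, dict], i: int, j: int) -> Tuple[str, str]:
    return tuple(sorted([_min_leaf(subtrees[i]), _min_leaf(subtrees[j])]))


def _min_leaf(st: dict) -> str:
    if "leaf" in st:
        return st["leaf"]
    return min(_min_leaf(c) for c, _ in st["children"])


def _clamp_pair(li: float, lj: float) -> Tuple[float, float]:
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def _build_tree(tree: Tree, st: dict, parent: Optional[str], length: float) -> None:
    if "leaf" in st:
        tree.add_node(st["leaf"], parent, length, label=st["leaf"])
        return
    nid = tree.add_node(None, parent, length)
    for child, clen in st["children"]:
        _build_tree(tree, child, nid, clen)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------
def bootstrap(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> Tree:
    """NJ point tree with bootstrap supports (percent) on internal nodes.

    Columns are resampled with replacement; support is the fraction of
    replicate trees containing each bipartition of the point tree.  With
    ``n_reps=0`` the point tree is returned with supports left unset.
    """
    if aln.n_cols < 1:
        raise ValueError("empty alignment")
    point = neighbor_joining(distances(aln, correction))
    if n_reps == 0:
        return point
    rng = np.random.default_rng(seed)
    counts: Dict[frozenset, int] = {}
    target = point.bipartitions()
    for b in target:
        counts[b] = 0
    cols = [[s[c] for s in aln.seqs] for c in range(aln.n_cols)]
    for _ in range(n_reps):
        pick = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rows = ["".join(cols[c][r] for c in pick) for r in range(len(aln.ids))]
        try:
            rep = neighbor_joining(distances(Alignment(list(aln.ids), rows), correction))
        except ValueError:  # a pair may share no ungapped columns in a resample
            continue
        for b in rep.bipartitions():
            if b in counts:
                counts[b] += 1
    all_labels = frozenset(l for l in point.leaf_labels())
    for nid in point.preorder():
        if nid == point.root or point.is_leaf(nid):
            continue
        side = frozenset(point.nodes[l].label or l for l in point.leaves(nid))
        key = min(side, all_labels - side, key=lambda s: (len(s), sorted(s)))
        if key in counts:
            point.nodes[nid].support = 100.0 * counts[key] / n_reps
    return point


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------
@dataclass
class PhyloModel:
    """Reversible substitution model: exchangeabilities + frequencies.

    Default is the Poisson (equal-exchangeability) model; any reversible
    matrix may be supplied.  ``alpha`` switches on discrete-Gamma rate
    variation with ``k`` equal-probability categories (category means)."""

    exchangeability: Optional[np.ndarray] = None  # (20,20) symmetric, None = equal
    frequencies: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    alpha: Optional[float] = None
    k_categories: int = 4

    def rate_matrix(self) -> np.ndarray:
        ex = self.exchangeability
        if ex is None:
            ex = np.ones((20, 20))
        Q = ex * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise to one expected substitution per unit branch length
        rate = -float(self.frequencies @ np.diag(Q))
        return Q / rate

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        a, k = self.alpha, self.k_categories
        # mean rate of each equal-probability slice of Gamma(a, 1/a)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        rates = np.empty(k)
        for i in range(k):
            lo, hi = edges[i], edges[i + 1]
            mass_lo = gamma_dist.cdf(lo, a + 1, scale=1.0 / a)
            mass_hi = gamma_dist.cdf(hi, a + 1, scale=1.0 / a) if np.isfinite(hi) else 1.0
            rates[i] = (mass_hi - mass_lo) * k
        return rates


def loglik(tree: Tree, aln: Alignment, model: Optional[PhyloModel] = None) -> float:
    """Felsenstein pruning log-likelihood of the alignment on the tree.

    Gap/X columns contribute a flat partial likelihood (missing data).
    """
    model = model or PhyloModel()
    leaf_map = tree.label_to_leaf()
    if set(leaf_map) != set(aln.ids):
        raise ValueError("tree leaves and alignment rows differ")
    Q = model.rate_matrix()
    freqs = model.frequencies
    rates = model.category_rates()
    # site patterns
    cols = np.array([[s[c] for s in aln.seqs] for c in range(aln.n_cols)])
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    row_of = {rid: i for i, rid in enumerate(aln.ids)}
    code = {a: i for i, a in enumerate(ALPHABET)}
    post = list(tree.postorder())
    total = 0.0
    P_cache = {}
    per_rate_site_likes = []
    for rate in rates:
        P = {}
        for nid in post:
            if nid == tree.root:
                continue
            t = tree.nodes[nid].length * rate
            P[nid] = expm(Q * t)
        # partials: node -> (n_patterns, 20)
        partial: Dict[str, np.ndarray] = {}
        for nid in post:
            if tree.is_leaf(nid):
                lab = tree.nodes[nid].label or nid
                obs = patterns[:, row_of[lab]]
                L = np.ones((len(patterns), 20))
                for pi, ch in enumerate(obs):
                    if ch in code:
                        L[pi] = 0.0
                        L[pi, code[ch]] = 1.0
                partial[nid] = L
            else:
                L = np.ones((len(patterns), 20))
                for c in tree.nodes[nid].children:
                    L = L * (partial[c] @ P[c].T)
                partial[nid] = L
        site_like = partial[tree.root] @ freqs
        per_rate_site_likes.append(site_like)
    site_like = np.mean(per_rate_site_likes, axis=0)
    if np.any(site_like <= 0):
        return -math.inf
    return float(np.log(site_like) @ counts)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------
def concatenate(
    alignments: Dict[str, Alignment],
    genome_of: Dict[str, str],
    copy_scores: Optional[Dict[str, float]] = None,
) -> Alignment:
    """Concatenate per-gene alignments into one genome-level alignment.

    Rows of the input alignments are gene copies; ``genome_of`` maps each
    gene id to its genome.  A genome missing a gene gets a gap block; a
    genome with several copies keeps the one with the highest value in
    ``copy_scores`` (e.g. family-HMM forward score), ties and missing scores
    resolved by gene id.
    """
    genomes = sorted({genome_of[g] for aln in alignments.values() for g in aln.ids})
    out_rows = {g: [] for g in genomes}
    col_source: List[str] = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        width = aln.n_cols
        col_source.extend([gene] * width)
        per_genome: Dict[str, List[str]] = {}
        for rid in aln.ids:
            per_genome.setdefault(genome_of[rid], []).append(rid)
        for g in genomes:
            cands = per_genome.get(g)
            if not cands:
                out_rows[g].append("-" * width)
                continue
            best = max(cands, key=lambda r: ((copy_scores or {}).get(r, 0.0), [-ord(c) for c in r]))
            out_rows[g].append(aln.row(best))
    return Alignment(ids=genomes, seqs=["".join(out_rows[g]) for g in genomes],
                     col_source=col_source)
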
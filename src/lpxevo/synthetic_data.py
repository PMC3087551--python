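"""Synthetic genomes with known evolutionary history.

Generates a species tree (Yule process), gene-family histories under a
per-branch duplication/loss model, protein sequences evolved along the tree
with optional invariant motif blocks, and per-genome gene orders with
planted syntenic clusters and gene fusions.  Every planted event is written
to a :class:`TruthLog` so downstream inference stages can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trees import Tree

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------
@dataclass
class FamilyHistory:
    family: str
    gain_branch: str
    # events: list of (branch_id, kind, copy_id, new_copy_id|None)
    events: List[Tuple[str, str, int, Optional[int]]] = field(default_factory=list)
    # per-leaf surviving copy ids
    leaf_copies: Dict[str, List[int]] = field(default_factory=dict)

    def copy_counts(self) -> Dict[str, int]:
        return {leaf: len(v) for leaf, v in self.leaf_copies.items()}

    @property
    def duplication_branches(self) -> List[str]:
        return [b for b, k, _, _ in self.events if k == "dup"]

    @property
    def loss_branches(self) -> List[str]:
        return [b for b, k, _, _ in self.events if k == "loss"]


@dataclass
class TruthLog:
    gain_branches: Dict[str, str] = field(default_factory=dict)
    duplications: Dict[str, List[str]] = field(default_factory=dict)
    losses: Dict[str, List[str]] = field(default_factory=dict)
    presence: Dict[str, Dict[str, int]] = field(default_factory=dict)  # genome -> family -> count
    motif_positions: Dict[str, List[int]] = field(default_factory=dict)  # gene id -> block starts
    clusters: Dict[str, List[str]] = field(default_factory=dict)  # genome -> ordered gene ids
    fusions: List[Dict[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLog":
        obj = cls()
        obj.__dict__.update(json.loads(text))
        return obj


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------
def simulate_species_tree(n_taxa: int, seed: int, birth_rate: float = 6.0) -> Tree:
    """Yule (pure-birth) species tree with `n_taxa` leaves.

    Branch lengths are in expected substitutions per site; the default
    birth rate puts root-to-tip depths near ln(n)/birth_rate ~ 0.5 for a
    few dozen taxa — within-phylum-like protein divergence, where
    single-query search finds most members and profile searches add the
    remote ones.
    """
    if n_taxa < 3:
        raise ValueError(f"n_taxa must be >= 3, got {n_taxa}")
    rng = np.random.default_rng(seed)
    t = Tree()
    root = t.add_node("N0", None, 0.0)
    active = []
    for _ in range(2):
        nid = t.add_node(f"N{len(t.nodes)}", root, 0.0)
        active.append(nid)
    # grow: at each event pick a random active lineage to split; all active
    # lineages accrue the exponential waiting time
    while len(active) < n_taxa:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for nid in active:
            t.nodes[nid].length += wait
        i = int(rng.integers(k))
        parent = active.pop(i)
        for _ in range(2):
            nid = t.add_node(f"N{len(t.nodes)}", parent, 0.0)
            active.append(nid)
    # final stretch to the present
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for nid in active:
        t.nodes[nid].length += wait
    # label leaves in a stable order
    for i, leaf in enumerate(sorted(t.leaves())):
        t.nodes[leaf].label = f"G{i+1:02d}"
    return t


# ---------------------------------------------------------------------------
# family histories (duplication / loss along the species tree)
# ---------------------------------------------------------------------------
def simulate_family_histories(
    tree: Tree,
    n_families: int,
    dup_rate: float,
    loss_rate: float,
    gain_branches: Optional[Dict[str, str]] = None,
    seed: int = 0,
    family_names: Optional[Sequence[str]] = None,
    forced_duplications: Optional[Dict[str, List[str]]] = None,
    forced_losses: Optional[Dict[str, List[str]]] = None,
) -> Tuple[List[FamilyHistory], TruthLog]:
    """Evolve gene-copy counts along the species tree.

    Each surviving copy, on each branch strictly below the family's gain
    branch, is independently lost with probability ``loss_rate`` and (if not
    lost) duplicated with probability ``dup_rate``.  Forced events override
    the coin flips on the named branches.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    names = list(family_names) if family_names else [f"fam{i+1}" for i in range(n_families)]
    if len(names) != n_families:
        raise ValueError("family_names length mismatch")
    gain_branches = dict(gain_branches or {})
    for fam in names:
        gain_branches.setdefault(fam, tree.root)
    for fam, b in gain_branches.items():
        if b not in tree.nodes:
            raise ValueError(f"unknown gain branch {b!r} for family {fam!r}")

    histories: List[FamilyHistory] = []
    truth = TruthLog()
    for fam in names:
        gain = gain_branches[fam]
        hist = FamilyHistory(family=fam, gain_branch=gain)
        counter = [0]

        def fresh() -> int:
            counter[0] += 1
            return counter[0]

        forced_d = set((forced_duplications or {}).get(fam, []))
        forced_l = set((forced_losses or {}).get(fam, []))

        def descend(node: str, copies: List[int], at_gain: bool) -> None:
            if not at_gain:
                surviving: List[int] = []
                force_loss = node in forced_l
                force_dup = node in forced_d
                for c in copies:
                    if force_loss:
                        lost, force_loss = True, False
                    else:
                        lost = loss_rate > 0 and rng.random() < loss_rate
                    if lost:
                        hist.events.append((node, "loss", c, None))
                        continue
                    surviving.append(c)
                    if force_dup:
                        dup, force_dup = True, False
                    else:
                        dup = dup_rate > 0 and rng.random() < dup_rate
                    if dup:
                        nc = fresh()
                        hist.events.append((node, "dup", c, nc))
                        surviving.append(nc)
                copies = surviving
            if not copies:
                return
            if tree.is_leaf(node):
                hist.leaf_copies[tree.nodes[node].label or node] = list(copies)
                return
            for ch in tree.nodes[node].children:
                descend(ch, list(copies), at_gain=False)

        descend(gain, [fresh()], at_gain=True)
        histories.append(hist)
        truth.gain_branches[fam] = gain
        truth.duplications[fam] = hist.duplication_branches
        truth.losses[fam] = hist.loss_branches

    for leaf in tree.leaf_labels():
        truth.presence[leaf] = {
            h.family: len(h.leaf_copies.get(leaf, [])) for h in histories
        }
    return histories, truth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------
@dataclass
class SubstitutionModel:
    """Symmetric 20-state substitution process, default equal exchangeabilities.

    Branch lengths are interpreted as expected substitutions per (free) site.
    """

    rates: Optional[np.ndarray] = None  # 20x20 rate matrix; None -> equal rates

    def p_change(self, t: float) -> float:
        """Probability a site differs from its parent after branch length t
        (equal-rates model only)."""
        if self.rates is not None:
            raise NotImplementedError("closed form only for the equal-rates model")
        k = len(AA)
        return (1 - 1 / k) * (1 - np.exp(-k / (k - 1) * t))

    def evolve(self, seq: str, t: float, rng: np.random.Generator,
               frozen: Optional[np.ndarray] = None) -> str:
        if self.rates is None:
            p = self.p_change(t)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            change = rng.random(len(arr)) < p
            if frozen is not None:
                change &= ~frozen
            idx = np.flatnonzero(change)
            for i in idx:
                cur = chr(arr[i])
                choices = [a for a in AA if a != cur]
                arr[i] = ord(choices[int(rng.integers(19))])
            return arr.tobytes().decode()
        from scipy.linalg import expm

        P = expm(self.rates * t)
        out = list(seq)
        for i, a in enumerate(seq):
            if frozen is not None and frozen[i]:
                continue
            out[i] = AA[rng.choice(len(AA), p=P[AA_INDEX[a]])]
        return "".join(out)


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random protein with a realistic (Robinson-Robinson) composition."""
    from .pairwise_search import BACKGROUND

    return "".join(AA[i] for i in rng.choice(20, size=length, p=BACKGROUND))


def plant_motif(length: int, blocks: Sequence[str], spacer: Tuple[int, int],
                rng: np.random.Generator) -> Tuple[str, np.ndarray, List[int]]:
    """Random protein with the given motif blocks embedded at fixed spacers.

    Returns (sequence, frozen-site mask, block start positions).
    """
    seq = list(random_protein(length, rng))
    frozen = np.zeros(length, dtype=bool)
    total_block = sum(len(b) for b in blocks)
    n_gaps = len(blocks) + 1
    avail = length - total_block
    if avail < n_gaps * spacer[0]:
        raise ValueError("sequence too short for motif")
    gaps = [int(rng.integers(spacer[0], min(spacer[1], avail // n_gaps) + 1)) for _ in range(n_gaps)]
    pos = gaps[0]
    starts = []
    for bi, block in enumerate(blocks):
        starts.append(pos)
        for j, res in enumerate(block):
            if res != "X":
                seq[pos + j] = res
                frozen[pos + j] = True
        pos += len(block) + gaps[bi + 1]
        if pos > length:
            pos = length
    return "".join(seq), frozen, starts


def evolve_sequences(
    tree: Tree,
    histories: List[FamilyHistory],
    root_seqs: Dict[str, str],
    subs_model: Optional[SubstitutionModel] = None,
    frozen_masks: Optional[Dict[str, np.ndarray]] = None,
    seed: int = 0,
) -> Dict[str, List[Tuple[str, str, str]]]:
    """Evolve each family's sequences along the species tree.

    Returns per-genome records ``(gene_id, family, sequence)``.  Duplicated
    copies evolve independently from the duplication branch onward; losses
    prune the lineage.  Gene ids are ``<family>|<genome>|c<copy>``.
    """
    model = subs_model or SubstitutionModel()
    rng = np.random.default_rng(seed)
    out: Dict[str, List[Tuple[str, str, str]]] = {lbl: [] for lbl in tree.leaf_labels()}
    for hist in histories:
        fam = hist.family
        root_seq = root_seqs[fam]
        if not root_seq:
            raise ValueError(f"empty root sequence for family {fam!r}")
        frozen = (frozen_masks or {}).get(fam)
        events_by_branch: Dict[str, List[Tuple[str, int, Optional[int]]]] = {}
        for b, k, c, nc in hist.events:
            events_by_branch.setdefault(b, []).append((k, c, nc))

        def descend(node: str, copies: Dict[int, str], at_gain: bool) -> None:
            cur = dict(copies)
            if not at_gain:
                # events happen at the top of the branch, then the survivors
                # (including fresh duplicates) evolve along the branch
                for kind, c, nc in events_by_branch.get(node, []):
                    if kind == "loss":
                        cur.pop(c, None)
                    elif kind == "dup" and c in cur:
                        cur[nc] = cur[c]
                t = tree.nodes[node].length
                if t > 0:
                    cur = {c: model.evolve(s, t, rng, frozen) for c, s in cur.items()}
            if not cur:
                return
            if tree.is_leaf(node):
                genome = tree.nodes[node].label or node
                keep = set(hist.leaf_copies.get(genome, []))
                for c in sorted(cur):
                    if c in keep:
                        out[genome].append((f"{fam}|{genome}|c{c}", fam, cur[c]))
                return
            for ch in tree.nodes[node].children:
                descend(ch, cur, at_gain=False)

        descend(hist.gain_branch, {1: root_seq}, at_gain=True)
    return out


def true_gene_tree(tree: Tree, hist: FamilyHistory) -> Optional[Tree]:
    """The gene tree implied by a family's recorded events.

    Duplication events create internal nodes on the recording branch;
    speciations create internal nodes at species-tree nodes; lineages with
    no surviving descendants are pruned.  Leaves are labelled with the same
    gene ids :func:`evolve_sequences` emits.  Returns None for < 2 leaves.
    """
    events_by_branch: Dict[str, Dict[int, Tuple[str, Optional[int]]]] = {}
    for b, k, c, nc in hist.events:
        events_by_branch.setdefault(b, {})[c] = (k, nc)

    def at_bottom(node: str, c: int) -> Optional[dict]:
        """Lineage of copy c from the bottom of branch `node` downward."""
        if tree.is_leaf(node):
            genome = tree.nodes[node].label or node
            if c in hist.leaf_copies.get(genome, []):
                return {"leaf": f"{hist.family}|{genome}|c{c}", "length": 0.0}
            return None
        subs = [lineage(ch, c) for ch in tree.nodes[node].children]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]
        return {"children": subs, "length": 0.0}

    def lineage(node: str, c: int) -> Optional[dict]:
        """Lineage of copy c entering the top of branch `node`."""
        ev = events_by_branch.get(node, {}).get(c)
        t = tree.nodes[node].length
        if ev is not None and ev[0] == "loss":
            return None
        if ev is not None and ev[0] == "dup":
            nc = ev[1]
            kids = [s for s in (at_bottom(node, c), at_bottom(node, nc)) if s is not None]
            for kid in kids:  # the duplication sits at the top of the branch
                kid["length"] += t
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return {"children": kids, "length": 0.0}
        sub = at_bottom(node, c)
        if sub is not None:
            sub["length"] += t
        return sub

    # root lineage: copy 1 entering the gain branch (no events on it)
    root_sub = at_bottom(hist.gain_branch, 1)
    if root_sub is None:
        return None
    gt = Tree()

    def build(sub: dict, parent: Optional[str]) -> None:
        if "leaf" in sub:
            gt.add_node(sub["leaf"], parent, sub["length"], label=sub["leaf"])
            return
        nid = gt.add_node(None, parent, sub["length"])
        for ch in sub["children"]:
            build(ch, nid)

    build(root_sub, None)
    if len(gt.leaves()) < 2:
        return None
    return gt


# ---------------------------------------------------------------------------
# genome assembly: gene order, clusters, fusions
# ---------------------------------------------------------------------------
@dataclass
class GeneRecord:
    genome: str
    contig: str
    gene_id: str
    family_truth: str
    start: int
    end: int
    strand: str


def assemble_genomes(
    sequences: Dict[str, List[Tuple[str, str, str]]],
    cluster_spec: Optional[Sequence[str]] = None,
    cluster_gap: int = 0,
    fusion_pair: Optional[Tuple[str, str]] = None,
    fusion_prob: float = 0.0,
    n_decoys: int = 0,
    decoy_length: int = 200,
    seed: int = 0,
    truth: Optional[TruthLog] = None,
) -> Tuple[List[GeneRecord], Dict[str, str]]:
    """Lay the per-genome sequences onto a single contig each.

    Families named in ``cluster_spec`` are planted contiguously in that order
    (one copy per family, with at most ``cluster_gap`` decoy genes inserted
    between members); remaining copies and decoys are shuffled after them.
    With probability ``fusion_prob`` per genome the two ``fusion_pair``
    members are concatenated into a single record.  Coordinates are 0-based
    half-open and non-overlapping.
    """
    rng = np.random.default_rng(seed)
    records: List[GeneRecord] = []
    fasta: Dict[str, str] = {}
    for genome in sorted(sequences):
        genes = list(sequences[genome])
        order: List[Tuple[str, str, str]] = []
        cluster_ids: List[str] = []
        # fusion first: replace the two members by one record
        if fusion_pair and fusion_prob > 0:
            a_i = next((i for i, g in enumerate(genes) if g[1] == fusion_pair[0]), None)
            b_i = next((i for i, g in enumerate(genes) if g[1] == fusion_pair[1]), None)
            if a_i is not None and b_i is not None and rng.random() < fusion_prob:
                ga, gb = genes[a_i], genes[b_i]
                fused = (
                    f"{fusion_pair[0]}+{fusion_pair[1]}|{genome}|fused",
                    f"{fusion_pair[0]}+{fusion_pair[1]}",
                    ga[2] + gb[2],
                )
                genes = [g for i, g in enumerate(genes) if i not in (a_i, b_i)]
                genes.append(fused)
                if truth is not None:
                    truth.fusions.append(
                        {
                            "genome": genome,
                            "gene_id": fused[0],
                            "family_a": fusion_pair[0],
                            "family_b": fusion_pair[1],
                            "breakpoint": str(len(ga[2])),
                        }
                    )
        by_family: Dict[str, List[Tuple[str, str, str]]] = {}
        for g in genes:
            by_family.setdefault(g[1], []).append(g)
        used = set()
        if cluster_spec:
            for fam in cluster_spec:
                # a fused record stands in for either parent family
                cands = by_family.get(fam, []) or [
                    g for g in genes if fam in g[1].split("+") and g[0] not in used
                ]
                cands = [g for g in cands if g[0] not in used]
                if not cands:
                    continue
                g = cands[0]
                if order and cluster_gap > 0:
                    for _ in range(int(rng.integers(0, cluster_gap + 1))):
                        order.append(_decoy(genome, len(fasta) + len(order), decoy_length, rng))
                order.append(g)
                used.add(g[0])
                cluster_ids.append(g[0])
        rest = [g for g in genes if g[0] not in used]
        decoys = [_decoy(genome, 10_000 + i, decoy_length, rng) for i in range(n_decoys)]
        tail = rest + decoys
        perm = rng.permutation(len(tail))
        order.extend(tail[i] for i in perm)
        if truth is not None and cluster_ids:
            truth.clusters[genome] = cluster_ids
        pos = 0
        for gid, fam, seq in order:
            span = 3 * len(seq) + 3
            records.append(GeneRecord(genome, f"{genome}_c1", gid, fam, pos, pos + span, "+" if rng.random() < 0.5 else "-"))
            fasta[gid] = seq
            pos += span + int(rng.integers(1, 200))
    return records, fasta


def _decoy(genome: str, idx: int, length: int, rng: np.random.Generator) -> Tuple[str, str, str]:
    return (f"decoy|{genome}|d{idx}", "decoy", random_protein(length, rng))


def gene_table_to_tsv(records: List[GeneRecord]) -> str:
    lines = ["genome\tcontig\tgene_id\tfamily_truth\tstart\tend\tstrand"]
    for r in records:
        lines.append(f"{r.genome}\t{r.contig}\t{r.gene_id}\t{r.family_truth}\t{r.start}\t{r.end}\t{r.strand}")
    return "\n".join(lines) + "\n"


def gene_table_from_tsv(text: str) -> List[GeneRecord]:
    rows = text.strip().splitlines()
    out = []
    for line in rows[1:]:
        g, c, gid, fam, s, e, st = line.split("\t")
        out.append(GeneRecord(g, c, gid, fam, int(s), int(e), st))
    return out
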
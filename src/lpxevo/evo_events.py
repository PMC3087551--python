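"""Gene gain, loss and duplication inference.

Presence/absence of each enzyme family across genomes is summarised in a
count matrix; each family's history is reconstructed under Dollo parsimony
(one gain, losses as needed — the natural model for a biosynthetic pathway
that is far easier to lose than to reinvent), and duplications are placed
by classical LCA reconciliation of the rooted gene tree against the rooted
species tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .family_classifier import FamilyAssignment
from .trees import Tree


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------
def build_presence_matrix(
    assignments: Dict[str, List[FamilyAssignment]],
    genomes: Optional[Sequence[str]] = None,
    families: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Copy-count matrix (genomes x families) plus a provenance matrix.

    ``assignments`` maps genome -> assignment list; provenance cells carry
    the union of evidence kinds ("rbh", "hmm", "both", "").
    """
    genomes = sorted(genomes or assignments.keys())
    fams = sorted(families or {a.family for lst in assignments.values() for a in lst})
    counts = pd.DataFrame(0, index=genomes, columns=fams, dtype=int)
    prov = pd.DataFrame("", index=genomes, columns=fams, dtype=object)
    for genome, lst in assignments.items():
        if genome not in counts.index:
            raise ValueError(f"unknown genome {genome!r}")
        for a in lst:
            if a.family not in counts.columns:
                continue
            counts.loc[genome, a.family] += 1
            cur = set(filter(None, prov.loc[genome, a.family].split("+")))
            cur.add(a.evidence)
            prov.loc[genome, a.family] = "+".join(sorted(cur))
    prov = prov.map(lambda s: "both" if set(s.split("+")) >= {"rbh", "hmm"} else s)
    return counts, prov


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------
@dataclass
class EventSet:
    family: str
    gain_branch: str
    loss_branches: List[str] = field(default_factory=list)
    duplication_branches: List[str] = field(default_factory=list)
    implied_losses: int = 0

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "gain": self.gain_branch,
            "losses": sorted(self.loss_branches),
            "duplications": sorted(self.duplication_branches),
            "implied_losses": self.implied_losses,
        }


def dollo_infer(presence: Dict[str, bool], tree: Tree) -> Tuple[str, List[str]]:
    """Single-gain (Dollo) reconstruction of a presence column.

    The gain sits on the branch above the MRCA of all present leaves; the
    loss set is the maximal absent subtrees strictly below the gain.  This
    placement is loss-minimal among all single-gain reconstructions.
    """
    label_to_leaf = tree.label_to_leaf()
    unknown = set(presence) - set(label_to_leaf)
    if unknown:
        raise ValueError(f"genomes not in tree: {sorted(unknown)}")
    present_leaves = [label_to_leaf[g] for g, p in presence.items() if p]
    if not present_leaves:
        raise ValueError("all-absent column: no gain placeable")
    gain = tree.mrca(present_leaves)
    present_set = set(present_leaves)
    losses: List[str] = []

    def collect(nid: str) -> None:
        if tree.is_leaf(nid):
            if nid not in present_set:
                losses.append(nid)
            return
        for c in tree.nodes[nid].children:
            if _has_present(tree, c, present_set):
                collect(c)
            else:
                losses.append(c)

    collect(gain)
    return gain, sorted(losses)


def _has_present(tree: Tree, nid: str, present: set) -> bool:
    return any(l in present for l in tree.leaves(nid))


# ---------------------------------------------------------------------------
# gene-tree / species-tree LCA reconciliation
# ---------------------------------------------------------------------------
def reconcile(
    gene_tree: Tree,
    species_tree: Tree,
    leaf_map: Dict[str, str],
) -> Tuple[List[str], int]:
    """Classical LCA reconciliation.

    Each gene-tree node maps to the LCA of its leaves' species; a node whose
    mapping equals a child's mapping is a duplication, charged to the
    species-tree branch above the mapped node.  Returns the duplication
    branch multiset and the implied loss count.
    """
    sp_leaf = species_tree.label_to_leaf()
    gene_leaves = gene_tree.leaves()
    for gl in gene_leaves:
        glabel = gene_tree.nodes[gl].label or gl
        if glabel not in leaf_map:
            raise ValueError(f"gene leaf {glabel!r} has no species mapping")
        if leaf_map[glabel] not in sp_leaf:
            raise ValueError(f"species {leaf_map[glabel]!r} not in species tree")
    # depths for LCA walk
    depth = {n: species_tree.depth(n) for n in species_tree.nodes}

    def sp_lca(a: str, b: str) -> str:
        while a != b:
            if depth[a] < depth[b]:
                b = species_tree.nodes[b].parent
            else:
                a = species_tree.nodes[a].parent
        return a

    mapping: Dict[str, str] = {}
    duplications: List[str] = []
    implied_losses = 0
    for nid in gene_tree.postorder():
        if gene_tree.is_leaf(nid):
            glabel = gene_tree.nodes[nid].label or nid
            mapping[nid] = sp_leaf[leaf_map[glabel]]
            continue
        children = gene_tree.nodes[nid].children
        m = mapping[children[0]]
        for c in children[1:]:
            m = sp_lca(m, mapping[c])
        mapping[nid] = m
        is_dup = any(mapping[c] == m for c in children)
        if is_dup:
            duplications.append(m)
        for c in children:
            gap = depth[mapping[c]] - depth[m]
            implied_losses += max(0, gap - (0 if is_dup else 1))
    return duplications, implied_losses


def infer_events(
    family: str,
    presence: Dict[str, bool],
    species_tree: Tree,
    gene_tree: Optional[Tree] = None,
    leaf_map: Optional[Dict[str, str]] = None,
) -> EventSet:
    gain, losses = dollo_infer(presence, species_tree)
    ev = EventSet(family=family, gain_branch=gain, loss_branches=losses)
    if gene_tree is not None and len(gene_tree.leaves()) >= 2:
        dups, implied = reconcile(gene_tree, species_tree, leaf_map or {})
        ev.duplication_branches = dups
        ev.implied_losses = implied
    return ev


def events_to_json(events: Sequence[EventSet]) -> str:
    return json.dumps([e.to_dict() for e in events], indent=1, sort_keys=True)
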
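"""Light rooted/unrooted tree container shared by all pipeline stages.

Nodes are identified by string ids; the branch *above* a node shares the
node's id, so "branch b" always means the edge from ``parent(b)`` down to
``b``.  Newick serialisation is delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import dendropy


@dataclass
class Node:
    id: str
    parent: Optional[str] = None
    children: List[str] = field(default_factory=list)
    length: float = 0.0
    label: Optional[str] = None  # leaf label (genome id) or support string
    support: Optional[float] = None


class Tree:
    """Rooted tree; an unrooted tree is represented with a trifurcating root."""

    def __init__(self) -> None:
        self.nodes: Dict[str, Node] = {}
        self.root: Optional[str] = None
        self._counter = 0

    # -- construction -------------------------------------------------
    def new_id(self, prefix: str = "n") -> str:
        self._counter += 1
        return f"{prefix}{self._counter}"

    def add_node(
        self,
        node_id: Optional[str] = None,
        parent: Optional[str] = None,
        length: float = 0.0,
        label: Optional[str] = None,
    ) -> str:
        nid = node_id if node_id is not None else self.new_id()
        if nid in self.nodes:
            raise ValueError(f"duplicate node id {nid!r}")
        self.nodes[nid] = Node(id=nid, parent=parent, length=length, label=label)
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = nid
        else:
            self.nodes[parent].children.append(nid)
        return nid

    # -- queries ------------------------------------------------------
    def is_leaf(self, nid: str) -> bool:
        return not self.nodes[nid].children

    def leaves(self, nid: Optional[str] = None) -> List[str]:
        start = nid if nid is not None else self.root
        return [n for n in self.preorder(start) if self.is_leaf(n)]

    def leaf_labels(self) -> List[str]:
        return [self.nodes[n].label or n for n in self.leaves()]

    def label_to_leaf(self) -> Dict[str, str]:
        return {self.nodes[n].label or n: n for n in self.leaves()}

    def preorder(self, nid: Optional[str] = None) -> Iterator[str]:
        stack = [nid if nid is not None else self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.nodes[n].children))

    def postorder(self, nid: Optional[str] = None) -> Iterator[str]:
        out = list(self.preorder(nid))
        return iter(reversed(out))

    def ancestors(self, nid: str) -> Iterator[str]:
        p = self.nodes[nid].parent
        while p is not None:
            yield p
            p = self.nodes[p].parent

    def depth(self, nid: str) -> int:
        return sum(1 for _ in self.ancestors(nid))

    def mrca(self, leaf_ids: List[str]) -> str:
        if not leaf_ids:
            raise ValueError("mrca of empty set")
        paths = []
        for leaf in leaf_ids:
            path = [leaf] + list(self.ancestors(leaf))
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for i in range(min(len(p) for p in paths)):
            col = {p[i] for p in paths}
            if len(col) == 1:
                mrca = paths[0][i]
            else:
                break
        return mrca

    def branch_ids(self) -> List[str]:
        """Every node id names the branch above it (the root 'branch' is the stem)."""
        return list(self.preorder())

    def ladderized_leaves(self) -> List[str]:
        """Leaf order after sorting children by subtree size (ties by id)."""
        size: Dict[str, int] = {}
        for n in self.postorder():
            size[n] = 1 if self.is_leaf(n) else sum(size[c] for c in self.nodes[n].children)
        out: List[str] = []

        def walk(n: str) -> None:
            if self.is_leaf(n):
                out.append(n)
                return
            for c in sorted(self.nodes[n].children, key=lambda c: (size[c], c)):
                walk(c)

        walk(self.root)
        return out

    # -- editing ------------------------------------------------------
    def reroot_on_edge(self, nid: str, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the branch above `nid`."""
        if nid == self.root:
            return self.copy()
        new = Tree()
        old = self.nodes
        root_id = "root*"
        new.add_node(root_id, None, 0.0)
        frac_len = old[nid].length * fraction

        def copy_down(src: str, parent_new: str, length: float) -> None:
            n = old[src]
            new.add_node(src, parent_new, length, n.label)
            new.nodes[src].support = n.support
            for c in n.children:
                copy_down(c, src, old[c].length)

        # downhill side
        copy_down(nid, root_id, frac_len)
        # uphill side: walk ancestors, reversing parent/child
        prev, prev_new, carry = nid, root_id, old[nid].length - frac_len
        p = old[nid].parent
        while p is not None:
            n = old[p]
            new.add_node(p, prev_new, carry, n.label)
            new.nodes[p].support = old[prev].support
            for c in n.children:
                if c != prev:
                    copy_down(c, p, old[c].length)
            carry = n.length
            prev, prev_new, p = p, p, n.parent
        # the old root may now be a degree-2 node; suppress it
        new._suppress_unifurcations()
        return new

    def _suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for nid in list(self.nodes):
                n = self.nodes.get(nid)
                if n is None or n.parent is None or len(n.children) != 1:
                    continue
                child = self.nodes[n.children[0]]
                child.length += n.length
                child.parent = n.parent
                pc = self.nodes[n.parent].children
                pc[pc.index(nid)] = child.id
                del self.nodes[nid]
                changed = True

    def copy(self) -> "Tree":
        t = Tree()
        t.root = self.root
        t._counter = self._counter
        for nid, n in self.nodes.items():
            t.nodes[nid] = Node(n.id, n.parent, list(n.children), n.length, n.label, n.support)
        return t

    # -- newick (via dendropy) ----------------------------------------
    def to_newick(self, supports: bool = False, internal_ids: bool = False) -> str:
        dt = self._to_dendropy(supports=supports, internal_ids=internal_ids)
        return dt.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def _to_dendropy(self, supports: bool = False, internal_ids: bool = False) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=taxa)

        def build(nid: str, dnode: dendropy.Node) -> None:
            n = self.nodes[nid]
            dnode.edge.length = n.length
            if self.is_leaf(nid):
                dnode.taxon = taxa.new_taxon(n.label or nid)
            else:
                if internal_ids:
                    dnode.label = nid
                elif supports and n.support is not None:
                    dnode.label = f"{n.support:g}"
                for c in n.children:
                    build(c, dnode.new_child())

        build(self.root, dt.seed_node)
        return dt

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Internal labels that parse as numbers become supports; any other
        internal label is taken as the node id (round-trips internal_ids)."""
        dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        t = cls()

        def build(dnode: dendropy.Node, parent: Optional[str]) -> None:
            label = dnode.taxon.label if dnode.taxon else None
            is_leaf = not dnode.child_nodes()
            nid = None
            support = None
            if is_leaf and label:
                nid = label
            elif dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    nid = dnode.label
            if nid is None:
                nid = t.new_id()
            t.add_node(nid, parent, dnode.edge.length or 0.0, label)
            t.nodes[nid].support = support
            for c in dnode.child_nodes():
                build(c, nid)

        build(dt.seed_node, None)
        return t

    def bipartitions(self) -> set:
        """Non-trivial bipartitions as frozensets of leaf labels (smaller side)."""
        all_labels = frozenset(self.leaf_labels())
        out = set()
        for nid in self.preorder():
            if nid == self.root or self.is_leaf(nid):
                continue
            side = frozenset(self.nodes[l].label or l for l in self.leaves(nid))
            if len(side) < 2 or len(all_labels - side) < 2:
                continue
            out.add(min(side, all_labels - side, key=lambda s: (len(s), sorted(s))))
        return out

    def collapse_low_support(self, min_support: float) -> "Tree":
        """Contract internal edges whose support is below `min_support`
        (unset supports are kept).  Leaves and the root are untouched."""
        t = self.copy()
        changed = True
        while changed:
            changed = False
            for nid in list(t.nodes):
                n = t.nodes.get(nid)
                if (
                    n is None or n.parent is None or t.is_leaf(nid)
                    or n.support is None or n.support >= min_support
                ):
                    continue
                parent = t.nodes[n.parent]
                idx = parent.children.index(nid)
                parent.children[idx:idx + 1] = n.children
                for c in n.children:
                    t.nodes[c].parent = parent.id
                del t.nodes[nid]
                changed = True
        return t

    def midpoint_root(self) -> "Tree":
        """Root at the midpoint of the longest leaf-to-leaf path."""
        leaves = self.leaves()
        # distances from each leaf via simple traversal
        def dists_from(src: str) -> Dict[str, float]:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                n = stack.pop()
                nb = list(self.nodes[n].children)
                if self.nodes[n].parent is not None:
                    nb.append(self.nodes[n].parent)
                for m in nb:
                    if m in dist:
                        continue
                    edge = self.nodes[n].length if m == self.nodes[n].parent else self.nodes[m].length
                    dist[m] = dist[n] + edge
                    stack.append(m)
            return dist

        best = (-1.0, None, None)
        dmaps = {l: dists_from(l) for l in leaves}
        for a in leaves:
            for b in leaves:
                if a < b and dmaps[a][b] > best[0]:
                    best = (dmaps[a][b], a, b)
        total, a, b = best
        if total <= 0:
            return self.copy()
        # walk from a toward b accumulating length until half the path
        target = total / 2.0
        da = dmaps[a]
        db = dmaps[b]
        # nodes on the path: d(a,x)+d(x,b) == total
        path = [n for n in self.nodes if abs(da[n] + db[n] - total) < 1e-9]
        path.sort(key=lambda n: da[n])
        for i in range(1, len(path)):
            if da[path[i]] >= target - 1e-12:
                lo, hi = path[i - 1], path[i]
                # the edge between lo and hi belongs to whichever is the child
                child = hi if self.nodes[hi].parent == lo else lo
                frac = (target - da[lo]) / max(da[hi] - da[lo], 1e-300)
                if child == lo:
                    frac = 1.0 - frac
                return self.reroot_on_edge(child, fraction=1.0 - frac)
        return self.copy()
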
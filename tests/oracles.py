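"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, quadratic scans — and shares no code with the implementations under
test.
"""

from __future__ import annotations

import re

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# local alignment: exhaustive chain enumeration
# ---------------------------------------------------------------------------
def brute_local_score(a: Sequence[int], b: Sequence[int], sub: np.ndarray,
                      gop: float, gext: float) -> float:
    """Best local affine-gap alignment score by enumerating every chain of
    matched index pairs (strictly increasing in both sequences).  A gap run
    of length g costs gop + g*gext; unaligned flanks are free."""
    n, m = len(a), len(b)
    best = 0.0

    def extend(last_i: int, last_j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        for i in range(last_i + 1, n):
            for j in range(last_j + 1, m):
                cost = 0.0
                gi = i - last_i - 1
                gj = j - last_j - 1
                if gi:
                    cost += gop + gext * gi
                if gj:
                    cost += gop + gext * gj
                extend(i, j, score - cost + sub[a[i], b[j]])

    for i in range(n):
        for j in range(m):
            extend(i, j, sub[a[i], b[j]])
    return best


# ---------------------------------------------------------------------------
# profile HMM: explicit path enumeration (no DP)
# ---------------------------------------------------------------------------
def enumerate_forward_odds(hmm, x: Sequence[int]) -> float:
    """Sum of odds-weighted probabilities over *every* state path that emits
    the full sequence, in the same local model (N/B/M/I/D/E/C flanks) as the
    forward kernel.  Pure DFS; exponential, for tiny models only."""
    L = len(x)
    M = hmm.length
    r = L / (L + 1.0)
    odds = hmm.match_emissions / hmm.background
    t = hmm.t
    total = 0.0

    def from_E(pos: int, p: float) -> None:
        nonlocal total
        # C emits the remaining residues (odds 1), then exits
        total += p * (r ** (L - pos)) * (1.0 - r)

    def from_M(j: int, pos: int, p: float) -> None:
        # M_j emits x[pos]
        if pos >= L:
            return
        p = p * odds[j, x[pos]]
        pos += 1
        from_E(pos, p * hmm.exit[j])
        if j < M:
            from_M(j + 1, pos, p * t["MM"][j])
            from_D(j + 1, pos, p * t["MD"][j])
        from_I(j, pos, p * t["MI"][j])

    def from_I(j: int, pos: int, p: float) -> None:
        if pos >= L:
            return
        pos += 1  # insert emits background (odds 1)
        if j < M:
            from_M(j + 1, pos, p * t["IM"][j])
        from_I(j, pos, p * t["II"][j])

    def from_D(j: int, pos: int, p: float) -> None:
        if j < M:
            from_M(j + 1, pos, p * t["DM"][j])
            from_D(j + 1, pos, p * t["DD"][j])
        # a path ending in a delete state never reaches E (exit is M-only)

    for n_flank in range(L + 1):  # N emits n_flank residues then enters B
        pb = (r ** n_flank) * (1.0 - r)
        for j in range(1, M + 1):
            from_M(j, n_flank, pb * hmm.entry[j])
    null = (r ** L) * (1.0 - r)
    return total / null


# ---------------------------------------------------------------------------
# motif scanning: bounded-repetition lazy regex
# ---------------------------------------------------------------------------
def regex_motif_matches(seq: str, pattern) -> List[List[int]]:
    """Non-overlapping leftmost matches via the re module with lazy bounded
    spacers; returns per-match block start lists."""
    parts = []
    for bi, block in enumerate(pattern.blocks):
        if bi > 0:
            lo, hi = pattern.spacers[bi - 1]
            parts.append(f"[A-Z]{{{lo},{hi}}}?")
        body = "".join(
            "[A-Z]" if not alts else
            (re.escape(next(iter(alts))) if len(alts) == 1 else "[" + "".join(sorted(alts)) + "]")
            for alts in block
        )
        parts.append(f"({body})")
    rx = re.compile("".join(parts))
    out = []
    for m in rx.finditer(seq.upper()):
        out.append([m.start(g) for g in range(1, len(pattern.blocks) + 1)])
    return out


# ---------------------------------------------------------------------------
# Dollo parsimony: brute force over all gain placements
# ---------------------------------------------------------------------------
def brute_dollo(tree, present_labels: set) -> Tuple[int, str]:
    """Minimum loss count over every valid single-gain branch, with the
    loss set defined as maximal absent subtrees below the gain.  Returns
    (min losses, a best gain branch)."""
    l2n = tree.label_to_leaf()
    present_nodes = {l2n[g] for g in present_labels}
    best = None
    for gain in tree.preorder():
        leaves_below = set(tree.leaves(gain))
        if not present_nodes <= leaves_below:
            continue
        losses = 0
        stack = [gain]
        while stack:
            nid = stack.pop()
            if tree.is_leaf(nid):
                if nid not in present_nodes:
                    losses += 1
                continue
            for c in tree.nodes[nid].children:
                if any(l in present_nodes for l in tree.leaves(c)):
                    stack.append(c)
                else:
                    losses += 1
        if best is None or losses < best[0]:
            best = (losses, gain)
    return best


# ---------------------------------------------------------------------------
# max-gap clusters: quadratic window enumeration
# ---------------------------------------------------------------------------
def brute_clusters(families_in_order: List[Optional[str]], targets: set,
                   max_gap: int) -> List[Tuple[int, ...]]:
    """All maximal index windows of target genes whose consecutive target
    members are separated by <= max_gap non-targets; >= 2 members."""
    idx = [i for i, f in enumerate(families_in_order) if f in targets]
    if not idx:
        return []
    groups: List[List[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [tuple(g) for g in groups if len(g) >= 2]


# ---------------------------------------------------------------------------
# duplication/loss branching process: independent simulator + closed form
# ---------------------------------------------------------------------------
def mc_mean_leaf_copies(tree, dup_rate: float, loss_rate: float,
                        n_reps: int, seed: int) -> float:
    """Monte-Carlo mean copy count per leaf for a family gained at the root,
    via a from-scratch re-simulation of the per-branch per-copy model."""
    rng = np.random.default_rng(seed)
    leaves = tree.leaves()
    totals = 0.0
    children = {n: tree.nodes[n].children for n in tree.nodes}
    for _ in range(n_reps):
        counts: Dict[str, int] = {tree.root: 1}
        stack = [tree.root]
        while stack:
            nid = stack.pop()
            k = counts[nid]
            for c in children[nid]:
                surv = 0
                for _c in range(k):
                    if rng.random() < loss_rate:
                        continue
                    surv += 1
                    if rng.random() < dup_rate:
                        surv += 1
                counts[c] = surv
                if surv:
                    stack.append(c)
        totals += sum(counts.get(l, 0) for l in leaves) / len(leaves)
    return totals / n_reps


def expected_leaf_copies(tree, dup_rate: float, loss_rate: float) -> float:
    """Closed-form expectation: each branch multiplies the expected copy
    count by (1 - loss)(1 + dup)."""
    factor = (1.0 - loss_rate) * (1.0 + dup_rate)
    total = 0.0
    leaves = tree.leaves()
    for leaf in leaves:
        k = sum(1 for _ in tree.ancestors(leaf))  # branches below the root
        total += factor ** k
    return total / len(leaves)


def surviving_duplications(tree, hist) -> int:
    """Planted duplications observable in the gene tree: both the parent and
    the daughter lineage must reach an extant copy *below the duplication
    branch*.  Computed from the raw event list by branch-scoped set closure
    (copy ids propagate into every descendant subtree, so both the copy
    closure and the alive set are restricted to the subtree of the event)."""
    n = 0
    for b, kind, c, nc in hist.events:
        if kind != "dup":
            continue
        below = set(tree.preorder(b))
        # descendant-copy edges from dup events strictly below b
        children: Dict[int, List[int]] = {}
        for b2, k2, c2, nc2 in hist.events:
            if k2 == "dup" and b2 in below and b2 != b:
                children.setdefault(c2, []).append(nc2)
        alive = {
            cp
            for leaf in tree.leaves(b)
            for cp in hist.leaf_copies.get(tree.nodes[leaf].label or leaf, [])
        }

        def closure(seed: int) -> set:
            out, stack = {seed}, [seed]
            while stack:
                x = stack.pop()
                for y in children.get(x, []):
                    if y not in out:
                        out.add(y)
                        stack.append(y)
            return out

        side_new = closure(nc)
        side_old = closure(c) - side_new
        if side_new & alive and side_old & alive:
            n += 1
    return n
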
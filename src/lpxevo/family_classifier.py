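"""Paralog discrimination: motif scanning and clade-based labelling.

The metallophosphoesterase superfamily signature is a five-block motif
D - Xn - GD - Xn - GNH(E/D) - Xn - H - Xn - GHXH with variable spacers; the
third-block histidine-to-arginine substitution distinguishes LpxH (R) from
LpxH2 (H).  Genes that motif rules cannot separate are labelled by the
smallest well-supported reference-containing clade of a gene tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .trees import Tree

DEFAULT_SPACER = (1, 300)
# Block 3 of the superfamily signature is written GNH(E/D), but the
# histidine there is exactly the diagnostic position (H in LpxH2, R in
# LpxH), so the *scanning* pattern leaves it free and the classifier reads
# the residue afterwards.
FIVE_BLOCK_PATTERN = "D-x(1,300)-GD-x(1,300)-GNx[ED]-x(1,300)-H-x(1,300)-GHxH"


@dataclass
class MotifPattern:
    """Ordered residue blocks separated by bounded variable spacers.

    Each block is a list of per-position residue alternatives (a set; empty
    means 'any').  ``spacers[i]`` bounds the gap between block i and i+1.
    """

    blocks: List[List[Set[str]]]
    spacers: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("pattern needs >= 1 block")
        if len(self.spacers) != len(self.blocks) - 1:
            raise ValueError("need one spacer bound per inter-block gap")
        for lo, hi in self.spacers:
            if lo > hi:
                raise ValueError("spacer min must be <= max")

    @classmethod
    def parse(cls, text: str, default_spacer: Tuple[int, int] = DEFAULT_SPACER) -> "MotifPattern":
        """Parse the mini-language: blocks of residues (x = any position,
        [ST] = alternatives) joined by '-'; 'x(lo,hi)' elements are spacers.

        Example: ``D-x(1,300)-GD-x(1,300)-GNH[ED]-x(1,300)-H-x(1,300)-GHxH``
        """
        blocks: List[List[Set[str]]] = []
        spacers: List[Tuple[int, int]] = []
        pending_spacer: Optional[Tuple[int, int]] = None
        for tok in text.split("-"):
            tok = tok.strip()
            m = re.fullmatch(r"x\((\d+),(\d+)\)", tok, flags=re.IGNORECASE)
            if m:
                if not blocks:
                    raise ValueError("pattern cannot start with a spacer")
                pending_spacer = (int(m.group(1)), int(m.group(2)))
                continue
            positions: List[Set[str]] = []
            i = 0
            while i < len(tok):
                ch = tok[i]
                if ch == "[":
                    end = tok.index("]", i)
                    positions.append(set(tok[i + 1 : end].upper()))
                    i = end + 1
                elif ch in "xX":
                    positions.append(set())
                    i += 1
                else:
                    positions.append({ch.upper()})
                    i += 1
            if not positions:
                raise ValueError(f"empty block in pattern: {text!r}")
            if blocks:
                spacers.append(pending_spacer or default_spacer)
            pending_spacer = None
            blocks.append(positions)
        return cls(blocks=blocks, spacers=spacers)

    def block_length(self, b: int) -> int:
        return len(self.blocks[b])


def five_block_pattern() -> MotifPattern:
    return MotifPattern.parse(FIVE_BLOCK_PATTERN)


@dataclass
class MotifMatch:
    seq_id: str
    block_starts: List[int]
    block_residues: List[str]


def _block_at(seq: str, pos: int, block: List[Set[str]]) -> bool:
    if pos + len(block) > len(seq):
        return False
    for off, alts in enumerate(block):
        if alts and seq[pos + off] not in alts:
            return False
    return True


def scan_motif(seq: str, pattern: MotifPattern, seq_id: str = "seq") -> List[MotifMatch]:
    """All non-overlapping matches, leftmost-first with shortest spacers.

    Search order mirrors a lazy bounded-repetition regex: the scan start
    advances left to right; within a match, each spacer takes the smallest
    feasible length (backtracking on failure); after a match the scan
    resumes at the match end.
    """
    seq = seq.upper()
    out: List[MotifMatch] = []
    pos = 0
    n = len(seq)
    while pos < n:
        placed = _try_match(seq, pos, pattern)
        if placed is None:
            break
        starts = placed
        residues = [
            seq[s : s + pattern.block_length(b)] for b, s in enumerate(starts)
        ]
        out.append(MotifMatch(seq_id=seq_id, block_starts=starts, block_residues=residues))
        pos = starts[-1] + pattern.block_length(len(starts) - 1)
    return out


def _try_match(seq: str, from_pos: int, pattern: MotifPattern) -> Optional[List[int]]:
    first = pattern.blocks[0]
    for start in range(from_pos, len(seq) - len(first) + 1):
        if not _block_at(seq, start, first):
            continue
        rest = _place_rest(seq, start + len(first), pattern, 1)
        if rest is not None:
            return [start] + rest
    return None


def _place_rest(seq: str, pos: int, pattern: MotifPattern, b: int) -> Optional[List[int]]:
    if b == len(pattern.blocks):
        return []
    lo, hi = pattern.spacers[b - 1]
    block = pattern.blocks[b]
    for gap in range(lo, hi + 1):
        s = pos + gap
        if s + len(block) > len(seq):
            break
        if _block_at(seq, s, block):
            rest = _place_rest(seq, s + len(block), pattern, b + 1)
            if rest is not None:
                return [s] + rest
    return None


# ---------------------------------------------------------------------------
# LpxH vs LpxH2: the diagnostic third-block residue
# ---------------------------------------------------------------------------
def classify_h_vs_h2(match: MotifMatch) -> str:
    """Third block is GN[H/R](E/D); R marks LpxH, H marks LpxH2."""
    if len(match.block_residues) < 3:
        raise ValueError("match does not cover block 3")
    key = match.block_residues[2][2]
    if key == "R":
        return "LpxH"
    if key == "H":
        return "LpxH2"
    return "indeterminate"


def conservation_table(matches: Sequence[MotifMatch]) -> pd.DataFrame:
    """Per-block, per-position residue frequencies across matches."""
    rows = []
    for m in matches:
        for b, res in enumerate(m.block_residues):
            for p, ch in enumerate(res):
                rows.append((b + 1, p, ch))
    df = pd.DataFrame(rows, columns=["block", "position", "residue"])
    if df.empty:
        return df
    out = (
        df.groupby(["block", "position", "residue"]).size().rename("count").reset_index()
    )
    totals = out.groupby(["block", "position"])["count"].transform("sum")
    out["frequency"] = out["count"] / totals
    return out


# ---------------------------------------------------------------------------
# clade-based assignment on a reference-labelled gene tree
# ---------------------------------------------------------------------------
@dataclass
class FamilyAssignment:
    gene_id: str
    family: str
    evidence: str  # motif | diagnostic-residue | clade | rbh | hmm
    support: Optional[float] = None


def assign_by_clade(
    gene_tree: Tree,
    references: Dict[str, str],
    min_support: float = 70.0,
) -> List[FamilyAssignment]:
    """Label unlabelled leaves by their smallest well-supported clade whose
    reference members all share one family.

    Walking up from each gene, clades under ``min_support`` or without
    references are skipped; the first qualifying clade decides: one
    reference family -> that label, several -> unassigned (a larger clade
    can never resolve the conflict).
    """
    if not (0 <= min_support <= 100):
        raise ValueError("min_support must be in [0, 100]")
    leaf_ids = {gene_tree.nodes[l].label or l for l in gene_tree.leaves()}
    missing = set(references) - leaf_ids
    if missing:
        raise ValueError(f"reference genes absent from tree: {sorted(missing)}")
    label_of_leaf = {l: (gene_tree.nodes[l].label or l) for l in gene_tree.leaves()}
    out: List[FamilyAssignment] = []
    for leaf in gene_tree.leaves():
        gid = label_of_leaf[leaf]
        if gid in references:
            out.append(FamilyAssignment(gid, references[gid], "reference", 100.0))
            continue
        assigned = None
        for anc in gene_tree.ancestors(leaf):
            sup = gene_tree.nodes[anc].support
            if sup is not None and sup < min_support and anc != gene_tree.root:
                continue
            fams = {
                references[label_of_leaf[l]]
                for l in gene_tree.leaves(anc)
                if label_of_leaf[l] in references
            }
            if not fams:
                continue
            if len(fams) == 1:
                assigned = FamilyAssignment(gid, fams.pop(), "clade", sup)
            break
        out.append(assigned or FamilyAssignment(gid, "unassigned", "clade", None))
    return out
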
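"""Syntenic gene clusters and gene fusions.

A cluster is a maximal same-contig run of pathway genes with at most
``max_gap`` intervening non-pathway genes (strand-agnostic by default — an
operational definition; the gap ceiling is reported with results).  A
fusion is a single gene matching two distinct family models on
near-disjoint protein intervals, as in the lpxC/fabZ fusion gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .pairwise_search import Hit
from .synthetic_data import GeneRecord
from .trees import Tree


@dataclass
class GeneCluster:
    genome: str
    contig: str
    gene_ids: List[str]
    families: List[str]
    start: int
    end: int
    max_internal_gap: int

    @property
    def signature(self) -> str:
        return "-".join(self.families)

    @property
    def signature_unordered(self) -> str:
        return "-".join(sorted(self.families))


@dataclass
class FusionCall:
    gene_id: str
    family_a: str
    family_b: str
    interval_a: Tuple[int, int]
    interval_b: Tuple[int, int]
    overlap_fraction: float

    def __post_init__(self) -> None:
        # canonical order: by interval start, then family name
        if (self.interval_b, self.family_b) < (self.interval_a, self.family_a):
            self.family_a, self.family_b = self.family_b, self.family_a
            self.interval_a, self.interval_b = self.interval_b, self.interval_a


def find_clusters(
    gene_table: Sequence[GeneRecord],
    family_map: Dict[str, str],
    target_families: Sequence[str],
    max_gap: int = 3,
    same_strand: bool = False,
) -> List[GeneCluster]:
    """Maximal runs of target-family genes with <= max_gap intervening
    non-target genes per adjacent pair; >= 2 members; never across contigs."""
    targets = set(target_families)
    by_contig: Dict[Tuple[str, str], List[GeneRecord]] = {}
    for r in gene_table:
        by_contig.setdefault((r.genome, r.contig), []).append(r)
    clusters: List[GeneCluster] = []
    for (genome, contig), recs in sorted(by_contig.items()):
        starts = [r.start for r in recs]
        if starts != sorted(starts):
            warnings.warn(f"gene table unsorted on {genome}/{contig}; sorting by start")
            recs = sorted(recs, key=lambda r: r.start)
        run: List[Tuple[int, GeneRecord]] = []

        def flush() -> None:
            if len(run) >= 2:
                members = [r for _, r in run]
                gaps = [run[i][0] - run[i - 1][0] - 1 for i in range(1, len(run))]
                clusters.append(
                    GeneCluster(
                        genome=genome,
                        contig=contig,
                        gene_ids=[m.gene_id for m in members],
                        families=[family_map.get(m.gene_id, "?") for m in members],
                        start=members[0].start,
                        end=members[-1].end,
                        max_internal_gap=max(gaps) if gaps else 0,
                    )
                )
            run.clear()

        for idx, r in enumerate(recs):
            fam = family_map.get(r.gene_id)
            if fam in targets:
                if run:
                    gap = idx - run[-1][0] - 1
                    strand_ok = not same_strand or r.strand == run[-1][1].strand
                    if gap > max_gap or not strand_ok:
                        flush()
                run.append((idx, r))
        flush()
    return clusters


def detect_fusions(
    hits_by_gene: Dict[str, List[Tuple[str, Hit]]],
    min_interval: int = 50,
    max_overlap: float = 0.2,
) -> List[FusionCall]:
    """Fusion calls from per-gene family-profile hits.

    ``hits_by_gene`` maps gene id -> [(family, hit)] where hit target
    intervals are on the protein.  A gene whose two best per-family hits
    cover near-disjoint intervals (overlap fraction <= ``max_overlap`` of
    the shorter interval), each at least ``min_interval`` long, is fused.
    """
    calls: List[FusionCall] = []
    for gid in sorted(hits_by_gene):
        best: Dict[str, Hit] = {}
        for fam, h in hits_by_gene[gid]:
            if fam not in best or h.bits > best[fam].bits:
                best[fam] = h
        fams = sorted(best)
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                ha, hb = best[fams[i]], best[fams[j]]
                la, lb = ha.tend - ha.tstart, hb.tend - hb.tstart
                if la < min_interval or lb < min_interval:
                    continue
                ov = max(0, min(ha.tend, hb.tend) - max(ha.tstart, hb.tstart))
                frac = ov / max(1, min(la, lb))
                if frac <= max_overlap:
                    calls.append(
                        FusionCall(gid, fams[i], fams[j],
                                   (ha.tstart, ha.tend), (hb.tstart, hb.tend), frac)
                    )
    return calls


def cluster_conservation_report(
    clusters: Sequence[GeneCluster],
    species_tree: Optional[Tree] = None,
    unordered: bool = False,
) -> pd.DataFrame:
    """Frequency of each cluster composition across genomes, with (when a
    species tree is given) the MRCA node localising the carriers."""
    rows: Dict[str, List[str]] = {}
    for c in clusters:
        sig = c.signature_unordered if unordered else c.signature
        rows.setdefault(sig, []).append(c.genome)
    out = []
    for sig in sorted(rows):
        genomes = sorted(set(rows[sig]))
        rec = {"signature": sig, "n_genomes": len(genomes), "genomes": ",".join(genomes)}
        if species_tree is not None:
            l2n = species_tree.label_to_leaf()
            present = [l2n[g] for g in genomes if g in l2n]
            rec["mrca"] = species_tree.mrca(present) if present else ""
        out.append(rec)
    return pd.DataFrame(out)


def clusters_to_tsv(clusters: Sequence[GeneCluster]) -> str:
    lines = ["genome\tcontig\tsignature\tstart\tend\tmax_gap\tgene_ids"]
    for c in clusters:
        lines.append(
            f"{c.genome}\t{c.contig}\t{c.signature}\t{c.start}\t{c.end}"
            f"\t{c.max_internal_gap}\t{','.join(c.gene_ids)}"
        )
    return "\n".join(lines) + "\n"


def fusions_to_tsv(calls: Sequence[FusionCall]) -> str:
    lines = ["gene_id\tfamily_a\tfamily_b\ta_start\ta_end\tb_start\tb_end\toverlap"]
    for f in calls:
        lines.append(
            f"{f.gene_id}\t{f.family_a}\t{f.family_b}\t{f.interval_a[0]}\t{f.interval_a[1]}"
            f"\t{f.interval_b[0]}\t{f.interval_b[1]}\t{f.overlap_fraction:.3f}"
        )
    return "\n".join(lines) + "\n"
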
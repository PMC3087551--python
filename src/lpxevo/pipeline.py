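"""End-to-end orchestration: simulate -> detect -> classify -> trees ->
events -> context -> report.

Every stage reads and writes plain files (FASTA / TSV / JSON / Newick) in
the run directory, so stages can be re-run and tested in isolation; the
manifest records seeds, thresholds and per-stage counts and is byte-stable
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__, evo_events, family_classifier, genome_context, msa_phylo
from . import pairwise_search as ps
from . import profile_hmm as ph
from . import synthetic_data as sd
from .family_classifier import FamilyAssignment
from .trees import Tree

PATHWAY_FAMILIES = ["lpxA", "lpxC", "lpxD", "lpxH", "lpxB", "lpxK", "waaA", "lpxL", "lpxM"]
CONCAT_FAMILIES = ["lpxA", "lpxC", "lpxD", "lpxB", "waaA", "lpxL"]
CLUSTER_SPEC = ["lpxD", "lpxC", "fabZ", "lpxA", "lpxB"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 1
    # simulation
    n_taxa: int = 20
    dup_rate: float = 0.05
    loss_rate: float = 0.05
    root_seq_length: int = 320  # the paper's average query length in aa
    n_decoys: int = 8
    fusion_prob: float = 0.3
    cluster_gap: int = 1
    # detection
    evalue_cutoff: float = 0.01
    avg_query_length: int = 320
    genome_size: int = 20_000
    hmm_calibration_n: int = 1000
    # trees
    bootstrap_reps: int = 1000
    gene_bootstrap_reps: int = 100
    outgroup: Optional[str] = None
    min_support: float = 70.0
    # context
    max_gap: int = 3
    fusion_min_interval: int = 50
    fusion_max_overlap: float = 0.2
    motif_pattern: str = family_classifier.FIVE_BLOCK_PATTERN

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _write_fasta(path: Path, records: Sequence[Tuple[str, str]]) -> None:
    _write(path, "".join(f">{i}\n{s}\n" for i, s in records))


def _read_fasta(path: Path) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def stage_simulate(cfg: RunConfig, out: Path) -> Dict[str, int]:
    rng = np.random.default_rng(cfg.seed)
    tree = sd.simulate_species_tree(cfg.n_taxa, seed=cfg.seed)
    families = PATHWAY_FAMILIES + ["fabZ"]
    histories, truth = sd.simulate_family_histories(
        tree, len(families), cfg.dup_rate, cfg.loss_rate,
        seed=cfg.seed + 1, family_names=families,
    )
    pattern = family_classifier.MotifPattern.parse(cfg.motif_pattern)
    root_seqs: Dict[str, str] = {}
    frozen: Dict[str, np.ndarray] = {}
    for fam in families:
        if fam == "lpxH":
            blocks = ["D", "GD", "GNRE", "H", "GHAH"]  # LpxH carries the R variant
            seq, mask, starts = sd.plant_motif(cfg.root_seq_length, blocks, (8, 25), rng)
            root_seqs[fam], frozen[fam] = seq, mask
            truth.motif_positions[fam] = starts
        else:
            root_seqs[fam] = sd.random_protein(cfg.root_seq_length, rng)
    seqs = sd.evolve_sequences(tree, histories, root_seqs, frozen_masks=frozen,
                               seed=cfg.seed + 2)
    records, fasta = sd.assemble_genomes(
        seqs, cluster_spec=CLUSTER_SPEC, cluster_gap=cfg.cluster_gap,
        fusion_pair=("lpxC", "fabZ"), fusion_prob=cfg.fusion_prob,
        n_decoys=cfg.n_decoys, seed=cfg.seed + 3, truth=truth,
    )
    _write(out / "species_tree.nwk", tree.to_newick(internal_ids=True) + "\n")
    _write(out / "gene_table.tsv", sd.gene_table_to_tsv(records))
    _write(out / "truth.json", truth.to_json())
    by_genome: Dict[str, List[Tuple[str, str]]] = {}
    for r in records:
        by_genome.setdefault(r.genome, []).append((r.gene_id, fasta[r.gene_id]))
    for genome, recs in sorted(by_genome.items()):
        _write_fasta(out / "proteomes" / f"{genome}.faa", recs)
    return {"genomes": len(by_genome), "genes": len(records), "families": len(families)}


def _load_proteomes(out: Path) -> Dict[str, List[Tuple[str, str]]]:
    return {
        p.stem: _read_fasta(p) for p in sorted((out / "proteomes").glob("*.faa"))
    }


def _pick_references(proteomes: Dict[str, List[Tuple[str, str]]],
                     families: Sequence[str]) -> Dict[str, Tuple[str, List[str]]]:
    """Per-family reference queries.

    The genome carrying the most families plays the part of the annotated
    E. coli K-12 genome; families it lost are seeded from another annotated
    genome, as supplementary queries from other species would be.  Gene ids
    carry the family annotation as their prefix.
    """
    per_genome: Dict[str, Dict[str, List[str]]] = {}
    for genome in sorted(proteomes):
        refs: Dict[str, List[str]] = {}
        for gid, _ in proteomes[genome]:
            fam = gid.split("|")[0]
            if fam in families:
                refs.setdefault(fam, []).append(gid)
        per_genome[genome] = refs
    primary = max(sorted(per_genome), key=lambda g: len(per_genome[g]))
    out: Dict[str, Tuple[str, List[str]]] = {}
    for fam in families:
        if fam in per_genome[primary]:
            out[fam] = (primary, per_genome[primary][fam])
        else:
            donor = next((g for g in sorted(per_genome) if fam in per_genome[g]), None)
            if donor is not None:
                out[fam] = (donor, per_genome[donor][fam])
    if not out:
        raise ValueError("no genome contains any reference family")
    return out


def stage_search(cfg: RunConfig, out: Path) -> Dict[str, int]:
    proteomes = _load_proteomes(out)
    families = PATHWAY_FAMILIES + ["fabZ"]
    refs = _pick_references(proteomes, families)
    sch = ps.default_scheme()
    search_cfg = ps.SearchConfig(cfg.evalue_cutoff, cfg.avg_query_length, cfg.genome_size)
    assignments = ps.reciprocal_best_hits(refs, proteomes, search_cfg, sch)
    lines = ["genome\tgene_id\tfamily\tevidence"]
    n = 0
    for fam in sorted(assignments):
        for genome in sorted(assignments[fam]):
            for gid in assignments[fam][genome]:
                lines.append(f"{genome}\t{gid}\t{fam}\trbh")
                n += 1
    _write(out / "rbh_assignments.tsv", "\n".join(lines) + "\n")
    _write(out / "reference.json",
           json.dumps({f: {"genome": g, "genes": ids} for f, (g, ids) in refs.items()},
                      sort_keys=True))
    return {"assignments": n, "reference_families": len(refs)}


def stage_hmm(cfg: RunConfig, out: Path) -> Dict[str, int]:
    proteomes = _load_proteomes(out)
    rbh = _read_assignments(out / "rbh_assignments.tsv")
    seq_of: Dict[str, str] = {gid: s for recs in proteomes.values() for gid, s in recs}
    lines = ["genome\tgene_id\tfamily\tevidence"]
    hit_lines = ["family\tgenome\t" + ps.hits_to_tsv([]).splitlines()[0]]
    n_hits = 0
    (out / "hmms").mkdir(parents=True, exist_ok=True)
    fams = sorted({a.family for lst in rbh.values() for a in lst})
    for fi, fam in enumerate(fams):
        members = [
            (a.gene_id, seq_of[a.gene_id])
            for genome in sorted(rbh)
            for a in rbh[genome]
            if a.family == fam
        ]
        if len(members) < 2:
            continue
        aln = msa_phylo.progressive_align(members)
        hmm = ph.build_hmm(list(zip(aln.ids, aln.seqs)))
        ph.calibrate(hmm, cfg.hmm_calibration_n, seed=cfg.seed + 100 + fi)
        _write(out / "hmms" / f"{fam}.json", hmm.to_json())
        for genome in sorted(proteomes):
            for h in ph.hmm_search(hmm, proteomes[genome], cfg.evalue_cutoff, query_id=fam):
                hit_lines.append(
                    f"{fam}\t{genome}\t{h.query}\t{h.target}\t{h.raw:g}\t{h.bits:.2f}"
                    f"\t{h.evalue:.3g}\t{h.qstart}\t{h.qend}\t{h.tstart}\t{h.tend}"
                )
                lines.append(f"{genome}\t{h.target}\t{fam}\thmm")
                n_hits += 1
    _write(out / "hmm_assignments.tsv", "\n".join(lines) + "\n")
    _write(out / "hmm_hits.tsv", "\n".join(hit_lines) + "\n")
    return {"hmm_hits": n_hits, "models": len(fams)}


def _read_assignments(path: Path) -> Dict[str, List[FamilyAssignment]]:
    out: Dict[str, List[FamilyAssignment]] = {}
    for line in path.read_text().splitlines()[1:]:
        if not line:
            continue
        genome, gid, fam, ev = line.split("\t")
        out.setdefault(genome, []).append(FamilyAssignment(gid, fam, ev))
    return out


def stage_classify(cfg: RunConfig, out: Path) -> Dict[str, int]:
    """Merge RBH and HMM evidence; scan the five-block motif and apply the
    H/R diagnostic to motif-bearing genes."""
    proteomes = _load_proteomes(out)
    rbh = _read_assignments(out / "rbh_assignments.tsv")
    hmm = _read_assignments(out / "hmm_assignments.tsv")
    pattern = family_classifier.MotifPattern.parse(cfg.motif_pattern)
    merged: Dict[str, Dict[Tuple[str, str], set]] = {}
    for src in (rbh, hmm):
        for genome, lst in src.items():
            for a in lst:
                merged.setdefault(genome, {}).setdefault((a.gene_id, a.family), set()).add(a.evidence)
    lines = ["genome\tgene_id\tfamily\tevidence\tmotif\tsubtype"]
    n_motif = 0
    for genome in sorted(merged):
        seq_of = dict(proteomes[genome])
        for (gid, fam), ev in sorted(merged[genome].items()):
            matches = family_classifier.scan_motif(seq_of[gid], pattern, seq_id=gid)
            subtype = ""
            if matches:
                n_motif += 1
                subtype = family_classifier.classify_h_vs_h2(matches[0])
            evs = "+".join(sorted(ev))
            lines.append(f"{genome}\t{gid}\t{fam}\t{evs}\t{len(matches)}\t{subtype}")
    _write(out / "assignments.tsv", "\n".join(lines) + "\n")
    return {"assigned_genes": sum(len(v) for v in merged.values()), "motif_genes": n_motif}


def _read_merged(out: Path) -> Dict[str, List[FamilyAssignment]]:
    res: Dict[str, List[FamilyAssignment]] = {}
    for line in (out / "assignments.tsv").read_text().splitlines()[1:]:
        if not line:
            continue
        genome, gid, fam, ev, _motif, _sub = line.split("\t")
        res.setdefault(genome, []).append(FamilyAssignment(gid, fam, ev))
    return res


def stage_tree(cfg: RunConfig, out: Path) -> Dict[str, int]:
    proteomes = _load_proteomes(out)
    merged = _read_merged(out)
    seq_of: Dict[str, str] = {gid: s for recs in proteomes.values() for gid, s in recs}
    fams = sorted({a.family for lst in merged.values() for a in lst})
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    alignments: Dict[str, msa_phylo.Alignment] = {}
    genome_of: Dict[str, str] = {}
    copy_scores: Dict[str, float] = {}
    hmm_dir = out / "hmms"
    n_trees = 0
    for fam in fams:
        members = []
        for genome in sorted(merged):
            for a in merged[genome]:
                if a.family == fam and a.gene_id in seq_of:
                    members.append((a.gene_id, seq_of[a.gene_id]))
                    genome_of[a.gene_id] = genome
        members = sorted(set(members))
        if len(members) < 2:
            continue
        aln = msa_phylo.progressive_align(members)
        alignments[fam] = aln
        _write(out / "alignments" / f"{fam}.afa", aln.to_fasta())
        hmm_path = hmm_dir / f"{fam}.json"
        if hmm_path.exists():
            hmm = ph.ProfileHMM.from_json(hmm_path.read_text())
            for gid, s in members:
                copy_scores[gid] = ph.forward_score(hmm, s)
        if len(members) >= 3:
            gt = msa_phylo.bootstrap(aln, cfg.gene_bootstrap_reps, seed=cfg.seed + 200 + n_trees)
            _write(out / "gene_trees" / f"{fam}.nwk", gt.to_newick(supports=True) + "\n")
            n_trees += 1
    concat = msa_phylo.concatenate(
        {f: alignments[f] for f in CONCAT_FAMILIES if f in alignments},
        genome_of, copy_scores,
    )
    _write(out / "alignments" / "concat.afa", concat.to_fasta())
    tree = msa_phylo.bootstrap(concat, cfg.bootstrap_reps, seed=cfg.seed + 300)
    if cfg.outgroup and cfg.outgroup in tree.label_to_leaf():
        tree = tree.reroot_on_edge(tree.label_to_leaf()[cfg.outgroup])
    else:
        tree = tree.midpoint_root()
    _write(out / "concat_tree.nwk", tree.to_newick(supports=True) + "\n")
    json.dump(copy_scores, open(out / "copy_scores.json", "w"), sort_keys=True)
    return {"gene_trees": n_trees, "concat_rows": len(concat.ids)}


def stage_events(cfg: RunConfig, out: Path) -> Dict[str, int]:
    species_tree = Tree.from_newick((out / "species_tree.nwk").read_text())
    merged = _read_merged(out)
    fams = sorted({a.family for lst in merged.values() for a in lst})
    counts, prov = evo_events.build_presence_matrix(merged, genomes=species_tree.leaf_labels(),
                                                   families=fams)
    counts.to_csv(out / "presence_matrix.tsv", sep="\t")
    prov.to_csv(out / "presence_provenance.tsv", sep="\t")
    events: List[evo_events.EventSet] = []
    for fam in fams:
        presence = {g: counts.loc[g, fam] > 0 for g in counts.index}
        if not any(presence.values()):
            continue
        gene_tree = None
        leaf_map = None
        gt_path = out / "gene_trees" / f"{fam}.nwk"
        if gt_path.exists():
            # weakly supported gene-tree edges are collapsed first so that
            # reconciliation does not turn tree-estimation noise into
            # duplication calls
            gene_tree = (
                Tree.from_newick(gt_path.read_text())
                .collapse_low_support(cfg.min_support)
                .midpoint_root()
            )
            leaf_map = {
                l: l.split("|")[1] for l in gene_tree.leaf_labels() if "|" in l
            }
        events.append(
            evo_events.infer_events(fam, presence, species_tree, gene_tree, leaf_map)
        )
    _write(out / "events.json", evo_events.events_to_json(events))
    return {"families_with_events": len(events),
            "total_duplications": sum(len(e.duplication_branches) for e in events)}


def stage_context(cfg: RunConfig, out: Path) -> Dict[str, int]:
    records = sd.gene_table_from_tsv((out / "gene_table.tsv").read_text())
    merged = _read_merged(out)
    family_map: Dict[str, str] = {}
    for lst in merged.values():
        for a in lst:
            family_map.setdefault(a.gene_id, a.family)
    targets = PATHWAY_FAMILIES + ["fabZ"]
    clusters = genome_context.find_clusters(records, family_map, targets, cfg.max_gap)
    _write(out / "clusters.tsv", genome_context.clusters_to_tsv(clusters))
    # fusions from per-gene HMM hits across family models
    hits_by_gene: Dict[str, List[Tuple[str, ps.Hit]]] = {}
    hh = (out / "hmm_hits.tsv").read_text().strip().splitlines()
    for line in hh[1:]:
        fam, genome, q, t, raw, bits, ev, qs, qe, ts, te = line.split("\t")
        hit = ps.Hit(q, t, float(raw), float(bits), float(ev),
                     int(qs), int(qe), int(ts), int(te))
        hits_by_gene.setdefault(t, []).append((fam, hit))
    fusions = genome_context.detect_fusions(hits_by_gene, cfg.fusion_min_interval,
                                            cfg.fusion_max_overlap)
    _write(out / "fusions.tsv", genome_context.fusions_to_tsv(fusions))
    species_tree = Tree.from_newick((out / "species_tree.nwk").read_text())
    report = genome_context.cluster_conservation_report(clusters, species_tree)
    report.to_csv(out / "cluster_report.tsv", sep="\t", index=False)
    return {"clusters": len(clusters), "fusions": len(fusions)}


def render_distribution(counts, species_tree: Tree, events: Sequence[evo_events.EventSet]) -> str:
    """Figure-2-style text table: genomes in ladderized tree order, one
    column per family; '.' marks absence, digits mark copy number."""
    fams = list(counts.columns)
    lines = ["genome\t" + "\t".join(fams)]
    placed = set()
    for leaf in species_tree.ladderized_leaves():
        g = species_tree.nodes[leaf].label or leaf
        if g not in counts.index:
            continue
        placed.add(g)
        marks = []
        for f in fams:
            c = int(counts.loc[g, f])
            marks.append("." if c == 0 else str(min(c, 9)))
        lines.append(g + "\t" + "\t".join(marks))
    unplaced = sorted(set(counts.index) - placed)
    if unplaced:
        lines.append("# unplaced: " + ",".join(unplaced))
    for e in sorted(events, key=lambda e: e.family):
        ann = f"# {e.family}: gain@{e.gain_branch}"
        if e.loss_branches:
            ann += " losses@" + ",".join(e.loss_branches)
        if e.duplication_branches:
            ann += " dups@" + ",".join(sorted(e.duplication_branches))
        lines.append(ann)
    return "\n".join(lines) + "\n"


def stage_report(cfg: RunConfig, out: Path) -> Dict[str, int]:
    import pandas as pd

    counts = pd.read_csv(out / "presence_matrix.tsv", sep="\t", index_col=0)
    species_tree = Tree.from_newick((out / "species_tree.nwk").read_text())
    raw = json.loads((out / "events.json").read_text())
    events = [
        evo_events.EventSet(e["family"], e["gain"], e["losses"], e["duplications"],
                            e["implied_losses"])
        for e in raw
    ]
    table = render_distribution(counts, species_tree, events)
    _write(out / "distribution.txt", table)
    return {"rows": len(table.splitlines())}


STAGES = [
    ("simulate", stage_simulate),
    ("search", stage_search),
    ("hmm", stage_hmm),
    ("classify", stage_classify),
    ("tree", stage_tree),
    ("events", stage_events),
    ("context", stage_context),
    ("report", stage_report),
]


def run(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = cfg.to_dict()
    cfg_echo.pop("out_dir")  # keep the manifest independent of run location
    manifest = {
        "version": __version__,
        "config": cfg_echo,
        "stages": {},
    }
    for name, fn in STAGES:
        try:
            stats = fn(cfg, out)
            manifest["stages"][name] = {"status": "ok", "counts": stats}
        except Exception as exc:  # partial failure keeps earlier artifacts
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            break
    _write(out / "manifest.json", json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
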
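# lpxevo

Comparative genomics of the Kdo₂-lipid A biosynthesis pathway.

Kdo₂-lipid A is the conserved glycolipid anchor of lipopolysaccharide in
the Gram-negative outer membrane. Its nine-enzyme biosynthesis pathway
(LpxA, LpxC, LpxD, LpxH, LpxB, LpxK, WaaA, LpxL, LpxM) has a patchy,
eventful history across bacteria: whole-pathway losses in endosymbionts,
lineage-specific duplications (LpxH/LpxH2, the LpxL-type acyltransferases
that spawned LpxM and LpxP), a conserved *lpxD-lpxC-fabZ-lpxA-lpxB* gene
cluster, and an *lpxC/fabZ* gene fusion in several phyla. `lpxevo` is a
tested, reusable pipeline for reconstructing that kind of history from
annotated proteomes — and, because public-genome studies are hard to
regression-test, it ships a synthetic-genome generator that plants every
kind of event it is supposed to recover and logs the ground truth.

For molecular evolution researchers and method developers who want each
stage of such an analysis to be a unit-testable function rather than a
shell pipeline.

## What it computes

| stage | method |
|---|---|
| homolog search | exact affine-gap Smith–Waterman, Karlin–Altschul statistics with a **constant** effective database length *m·n* = 320 aa × 20,000 genes = 6,400,000, cutoff E ≤ 0.01 |
| orthology | reciprocal best hits against a reference genome, with paralog retention for duplicated copies |
| remote members | Plan-7-style profile HMMs (forward log-odds, bits), E = 20,000 · P(S ≥ s) from a tail-anchored null fit |
| subfamily calls | five-block metallophosphoesterase motif **D**-Xn-**GD**-Xn-**GN·(E/D)**-Xn-**H**-Xn-**GHXH** with variable spacers; the third-block residue is diagnostic (R → LpxH, H → LpxH2); clade-based labels on reference-tagged gene trees |
| trees | progressive alignment, Poisson-corrected distances, neighbor joining, column bootstrap; fixed-tree likelihood by Felsenstein pruning with discrete-Γ rates; multi-gene concatenation (one copy per genome, best HMM score) |
| events | Dollo parsimony (single gain at the MRCA of present genomes, minimal losses as maximal absent subtrees) and gene-tree/species-tree LCA reconciliation for duplications |
| synteny | max-gap gene clusters (≤ *g* intervening genes, default 3) and fusion calls (one protein matching two family models on near-disjoint intervals) |

## Worked example

```python
from lpxevo import pipeline

cfg = pipeline.RunConfig(out_dir="run", seed=20260901, n_taxa=12,
                         n_decoys=4, bootstrap_reps=100,
                         gene_bootstrap_reps=25, hmm_calibration_n=500,
                         root_seq_length=150)
manifest = pipeline.run(cfg)       # or: lpxevo run-all --out-dir run --seed ...
print(open("run/distribution.txt").read())
```

This simulates 12 genomes under duplication/loss rates of 0.05 per copy
per branch, re-detects the families by reciprocal best hits plus profile
HMMs, and prints the presence/copy-number table in ladderized tree order
with inferred events as footnotes:

```
genome	fabZ	lpxA	lpxB	lpxC	lpxD	lpxH	lpxK	lpxL	lpxM	waaA
G12	1	1	.	1	.	1	1	1	1	1
G03	1	1	.	1	.	1	1	1	1	1
G04	1	1	.	1	.	1	1	1	2	.
...
# lpxC: gain@N0 dups@N4
# lpxD: gain@N2 losses@G08 dups@N4
# waaA: gain@N0 losses@G01,G04,G05,N3 dups@N1
```

A `.` is an absence; digits are detected copy numbers; `gain@`/`losses@`/
`dups@` name species-tree branches (the branch above the named node). Here
`lpxC` shows a duplication on the internal branch N4 and `waaA` has been
lost four times independently — the same kind of readout as a
presence/absence figure over real genomes, but with a `truth.json` next to
it that records what was actually planted.

Every stage also writes its own plain-file artifacts under `run/`
(`rbh_assignments.tsv`, `hmm_hits.tsv`, `gene_trees/*.nwk`,
`presence_matrix.tsv`, `events.json`, `clusters.tsv`, `fusions.tsv`), so
any step can be rerun or inspected in isolation. The same stages are
exposed as CLI subcommands (`lpxevo simulate|search|hmm|classify|tree|
events|context|report|run-all`).

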
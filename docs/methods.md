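# Methods

This note records the models implemented in `lpxevo`, the defaults that
matter, the numerical choices, and the limits of what the synthetic
benchmark shows.

## Homology search statistics

Pairwise search is exact affine-gap Smith–Waterman (BLOSUM62, gap open 11,
extend 1; a gap of length L costs 11 + L). Exact DP replaces heuristic
seeded search deliberately: at this scale it is affordable, and it makes
presence/absence calls conservative-compatible — anything a heuristic
would find, the exact DP also finds.

E-values follow Karlin–Altschul, `E = K·m·n_eff·exp(−λS)`, with the
database length held **constant** at `n_eff` = 320 aa (average query
length) × 20,000 (nominal genes per genome) = 6,400,000. Holding `n_eff`
fixed makes a score mean the same thing in a 600-gene endosymbiont and an
8,000-gene soil bacterium; "no hit" is then a property of the sequences,
not of proteome size. The cutoff is E ≤ 0.01 everywhere.

λ and K for the gapped scheme are fitted once by maximum likelihood of a
Gumbel distribution to Smith–Waterman scores of 5,000 random
background-composition pairs (length 150, seed 20260901): λ = 0.29953,
K = 0.07331. The exactly solvable ungapped λ (root of
Σ pᵢpⱼ e^{λ sᵢⱼ} = 1, here 0.3176) bounds the gapped λ from above and is
asserted in tests. Background residue frequencies are Robinson–Robinson
throughout — including in the synthetic-sequence generator, because a
composition mismatch between decoys and the calibration null is otherwise
itself a (spurious) signal.

Reciprocal best hits: each family has a reference query in an annotated
reference genome (the genome carrying the most families; families it has
lost are seeded from another genome, as supplementary queries from other
species would be). A gene is assigned to the family iff it hits the query
at E ≤ 0.01 and its own top hit back in the reference genome is a member
of the family's reference set. All reciprocally-confirmed hits are kept,
not just the top one, so duplicate copies (in-paralogs) survive.

## Profile HMMs

Models are Plan-7-style local profiles: match/insert/delete columns from a
seed alignment (match columns = residue occupancy ≥ 0.5), uniform entry
B→Mⱼ = 1/M, per-state exit probability 0.01 (last column exits with
probability 1), and N/C flank states emitting background with a geometric
length model r = L/(L+1), whose contribution cancels against the null in
the reported log-odds. Scores are forward log-odds in bits; Viterbi
supplies hit intervals. The forward recursion runs in scaled probability
space (per-row renormalisation), which keeps it pure multiply-add and fast
enough to score millions of null sequences.

Pseudocounts are fixed-weight background mixtures (Laplace-style), weight
1.0 on emissions but only 0.1 on transitions. The asymmetry is load-
bearing: with a dozen seed sequences, a weight-1.0 transition prior drags
tMM to ≈ 0.86 and taxes a 320-column traversal by ~70 bits, silencing
exactly the remote homologs profiles exist to find. Dirichlet-mixture
priors and multi-domain parsing are out of scope.

Null calibration: `E(S) = 20,000 · P(S ≥ s)`, the constant interpreted as
candidate sequences per genome-equivalent. P comes from a Gumbel whose
*tail* is anchored at the empirical 95th percentile of ≥ 500 (default
1,000) forward scores of random background sequences, with slope fixed at
the asymptotic λ = ln 2 per bit (log-odds scores obey the Chernoff bound
P(S ≥ s) ≤ 2^−s). A maximum-likelihood Gumbel fit was tried first and
rejected: against 200,000 empirical null scores it underestimates the tail
by two orders of magnitude at P ≈ 10⁻⁴, which multiplies false detections
far past their nominal expectation. The anchored-tail fit is conservative
(measured false detections fall below the nominal E), which biases the
pipeline toward missing borderline remote members rather than inventing
them.

## Alignment and trees

Progressive alignment: 3-mer distances → average-linkage guide tree
(scipy) → profile–profile global alignment under the expected BLOSUM62
column score with affine gaps (open 10, extend 0.5). For two sequences
this reduces exactly to Needleman–Wunsch, which is how it is tested.

Distances are p-distances over mutually ungapped columns, optionally
Poisson-corrected (−ln(1−p)); saturated pairs (p ≥ 1 is impossible, but
p → 1 under correction) are flagged and capped at the resolution of the
data. Trees come from Saitou–Nei neighbor joining with lexicographic
tie-breaks and negative-branch clamping (deficit moved to the sibling so
path lengths are preserved). Bootstrap support is the fraction of
column-resampled replicate NJ trees containing each bipartition of the
point tree; the default is 1,000 replicates.

Maximum likelihood appears only as fixed-tree scoring: Felsenstein
pruning over unique site patterns, any reversible exchangeability matrix
(default Poisson/equal rates), optional discrete-Γ with k = 4
equal-probability categories using category means. Tree *search* under ML
is intentionally absent — in this pipeline the tree is a scaffold for
event inference, and NJ topologies plus likelihood scoring cover that role
at a fraction of the cost. Likelihood is invariant under rerooting
(reversibility), which is property-tested.

Concatenation builds one row per genome across per-gene alignments
(default gene set: LpxA, LpxC, LpxD, LpxB, WaaA, LpxL); missing genes
become gap blocks, and of multiple copies the one with the highest
family-HMM forward score is kept. Rooting is by a named outgroup taxon
when configured, else midpoint.

## Subfamily classification

The metallophosphoesterase signature is scanned as five ordered blocks
with bounded variable spacers (default 1–300; the cap exists because an
unbounded Xn makes scan time pathological on repetitive sequences).
Matching is leftmost-first with shortest spacers and backtracking —
exactly the semantics of a lazy bounded-repetition regex, against which
the scanner is tested. Block 3 is scanned as `GNx[ED]`: the position the
superfamily consensus writes as H is precisely the diagnostic site
(H → LpxH2, R → LpxH), so the scanner leaves it free and
`classify_h_vs_h2` reads it. Per-block conservation is reported as a
frequency table, not enforced as a filter.

Genes that motif rules cannot separate are labelled by the smallest
well-supported clade (support ≥ 70, the figure-legend tier) of a gene
tree whose references all share one family; clades with conflicting
references escalate to unassigned, since a larger clade can only add
references.

## Event inference

Presence/absence columns are reconstructed under Dollo parsimony: one
gain, on the branch above the MRCA of present genomes, with losses at the
maximal absent subtrees below it. This placement is loss-minimal among
single-gain reconstructions (a higher gain only adds absent subtrees),
and is verified against brute-force enumeration of every gain placement.
Dollo is the right model here because a multi-enzyme biosynthetic pathway
is plausibly lost and implausibly re-invented; horizontal transfer is not
modelled. Consequence: a family truly gained at the root but absent from
an entire basal clade is inferred as gained later — with losses near the
root, the MRCA of the survivors underestimates the gain depth. That is a
property of Dollo, not a defect of the implementation.

Duplications come from LCA reconciliation of rooted gene trees against
the rooted species tree (a gene-tree node mapping to the same species
node as one of its children is a duplication; implied losses are counted
from mapping depth gaps). Gene trees are midpoint-rooted, and edges with
bootstrap support below the threshold are collapsed first — otherwise
tree-estimation noise is systematically converted into duplication calls
(LCA duplications are a lower bound only when the gene tree is true).

## The synthetic benchmark

The generator emulates the study conditions of a multi-phylum pathway
survey: a Yule species tree (default birth rate 6.0, i.e. root-to-tip
≈ ln n / 6 ≈ 0.5 expected substitutions/site for a few dozen taxa —
within-phylum-like divergence where single-query search finds most
members and profiles add the remote ones); 9 pathway families plus fabZ;
per-copy per-branch duplication and loss probabilities (default 0.05
each, applied on every branch strictly below the family's gain branch);
site-independent sequence evolution under a 20-state equal-rates model
(closed form P(change) = (19/20)(1 − e^{−20t/19}) is the test oracle),
with motif sites frozen; root proteins of 320 aa (the average enzyme
query length) sampled from Robinson–Robinson frequencies; gene orders
with the planted lpxD-lpxC-fabZ-lpxA-lpxB cluster, decoy genes, a
configurable lpxC+fabZ fusion probability (default 0.3 per genome), and
0-based half-open non-overlapping coordinates. Every planted event goes
into a JSON truth log, including the implied true gene tree per family.

What passing recovery tests shows: the detection, classification, and
event-inference machinery is correct and calibrated *under the generative
model* — no indels within families, no rate heterogeneity across sites or
lineages, no compositional drift, no horizontal transfer, no annotation
error, single-contig genomes. Real proteomes violate all of these, so
recovery rates here are upper bounds on real-data performance; the
benchmark's value is catching algorithmic and statistical errors, not
forecasting sensitivity on real genomes.

Duplication recovery is scored against *observable* planted events: a
duplication whose parent or daughter lineage left no extant copies below
the duplication branch is absent from every gene tree and unrecoverable
by any method; the observable count is computed by an independent
set-closure oracle over the raw event log.

## Problem sizes and determinism

Test and acceptance runs use 8–20 genomes, 320-aa proteins, 100–1,000
bootstrap replicates, 1,000-sequence HMM calibrations, and 200 × 20,000
null searches; the full acceptance script completes in a few minutes on
one CPU. All randomness flows through seeded numpy generators; identical
seeds reproduce byte-identical artifacts, which the end-to-end snapshot
test enforces against golden files.

## Known limitations

- Dollo gain placement under early losses (above) — inherent to the model.
- The conservative null tail trades borderline remote-homolog sensitivity
  for false-positive control.
- The motif spacer cap (300) would truncate matches in extremely long
  multi-domain proteins.
- Reconciliation on inferred (rather than true) gene trees still
  overcounts duplications when internal supports are high but wrong;
  collapsing at 70% mitigates, does not eliminate.
- tblastn-style six-frame DNA search is not implemented; inputs are
  annotated proteomes.
- 16S rRNA, if used, goes through the protein-style aligner as plain
  sequence; covariance-model alignment is out of scope.
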
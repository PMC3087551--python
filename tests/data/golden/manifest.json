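{
 "config": {
  "avg_query_length": 320,
  "bootstrap_reps": 100,
  "cluster_gap": 1,
  "dup_rate": 0.05,
  "evalue_cutoff": 0.01,
  "fusion_max_overlap": 0.2,
  "fusion_min_interval": 50,
  "fusion_prob": 0.3,
  "gene_bootstrap_reps": 25,
  "genome_size": 20000,
  "hmm_calibration_n": 500,
  "loss_rate": 0.05,
  "max_gap": 3,
  "min_support": 70.0,
  "motif_pattern": "D-x(1,300)-GD-x(1,300)-GNx[ED]-x(1,300)-H-x(1,300)-GHxH",
  "n_decoys": 4,
  "n_taxa": 12,
  "outgroup": null,
  "root_seq_length": 150,
  "seed": 20260901
 },
 "stages": {
  "classify": {
   "counts": {
    "assigned_genes": 104,
    "motif_genes": 15
   },
   "status": "ok"
  },
  "context": {
   "counts": {
    "clusters": 12,
    "fusions": 1
   },
   "status": "ok"
  },
  "events": {
   "counts": {
    "families_with_events": 10,
    "total_duplications": 5
   },
   "status": "ok"
  },
  "hmm": {
   "counts": {
    "hmm_hits": 104,
    "models": 10
   },
   "status": "ok"
  },
  "report": {
   "counts": {
    "rows": 23
   },
   "status": "ok"
  },
  "search": {
   "counts": {
    "assignments": 103,
    "reference_families": 10
   },
   "status": "ok"
  },
  "simulate": {
   "counts": {
    "families": 10,
    "genes": 167,
    "genomes": 12
   },
   "status": "ok"
  },
  "tree": {
   "counts": {
    "concat_rows": 12,
    "gene_trees": 10
   },
   "status": "ok"
  }
 },
 "version": "0.1.0"
}
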
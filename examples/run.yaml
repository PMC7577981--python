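# Full pipeline configuration: simulate -> genotype -> infer -> analyze -> cooccur
# Run with:  clonalevo run --config examples/run.yaml
out_dir: scratch/demo_run
seed: 1

simulate:
  n_mutations: 8
  n_cells: 3000
  ado: 0.058          # platform-style allele dropout
  n_snp_loci: 10      # germline-het SNPs for ADO estimation
  n_timepoints: 1

genotype:
  ambiguous_as_missing: false

infer:
  model_id: 2         # all cells, 1% FPR, sample-ADO as FNR
  fpr: 0.01
  chain_length: 20000
  n_chains: 2

analyze:
  threshold: 0.01     # clones under 1% of tumor cells are flagged

cooccur:
  levels: [cell, clone]
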
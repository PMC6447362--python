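# End-to-end demo: simulate an exon-biased dataset and run every stage.
out_dir: scratch/demo_run
seed: 17
log_level: INFO
params:
  flank_bp: 500
  n_bins: 16
  min_intron_bp: 100
  min_separation_bp: 1000
simulation:
  n_genes: 80
  f_exon: 3.0
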
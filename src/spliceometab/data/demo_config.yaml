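# End-to-end synthetic demonstration run: all six stages from one seed.
seed: 7
outdir: demo_out
stages: [simulate, diff-ir, site-features, da, sg-score, cohort-dist]
thresholds:
  fdr: 0.05
  dpsi: 0.02
  alpha: 0.05
  top_fraction: 0.05
simulation:
  n_genes: 100
  weak_fraction: 0.5
  depth: 200
  ir_effect: 0.3
  n_samples_per_group: 3
  n_cells: 1000
  sg_fraction: 0.4
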
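# Small end-to-end demo: one tissue, NHS/HS with 3 replicates each
# (the 6-library per-tissue layout), synthetic counts with 30 planted
# ceRNA triads. Runs in a few seconds.
seed: 0
outdir: demo_out
tissues: [hypothalamus]
conditions: [NHS, HS]
replicates: 3
simulate:
  n_features: {circRNA: 300, miRNA: 100, mRNA: 500}
  de_fraction: 0.3
  n_planted_triads: 30
  triad_coupling_strength: 0.9
  interaction_density: 0.05
thresholds:
  scc_threshold: -0.7
  pcc_threshold: 0.9
  sponge_alpha: 0.05
  fc_threshold: 2.0
  de_alpha: 0.05
  mrna_fdr: 0.05
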
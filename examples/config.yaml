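# Demo pipeline configuration: a coupled synthetic world, analyzed end to end.
#   specstruct run-all --config examples/config.yaml
out_dir: scratch/demo_world
seed: 7
simulate:
  enabled: true
  n_species: 12
  coupling: coupled
  n_sites: 1000
  missing_rate: 0.05
congruence:
  slices: 100
  replicates: 25
  models: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
  threshold: 0.02
popgen:
  max_missing: 0.2
  permutations: 199
comparative:
  min_n: 10
  signal_replicates: 199
  min_signal_tips: 8
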
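# Full-scale synthetic demo for the `weedfs run` subcommand:
#   weedfs run --config examples/demo.yaml --out results/demo
# Simulates a 2135-gene, 52 tumor / 50 normal study with contamination,
# then runs preprocess -> CIWO selection -> classifier -> 5-iteration
# repeated hold-out evaluation. Takes a few minutes on one core.
simulate:
  n_genes: 2135
  n_informative: 50
  samples_per_class: [52, 50]
  effect_size: 3.0
  raw_scale: true
  frac_missing: 0.01
  n_replicate_ids: 5
  n_flat_genes: 3
  seed: 0
ciwo:
  max_iter: 150   # budget scaled up for the 2135-feature search space
n_iterations: 5
base_seed: 0
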
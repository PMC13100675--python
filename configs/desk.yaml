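# Desk-scale presets: runnable in minutes on one CPU.
# Pass to the matching subcommand via --config; explicit CLI options win.

random_search:
  env: lorenz
  configs: 300
  tests: 25
  seed: 1

sample_size:
  env: lorenz
  n_grid: [10, 20, 50, 100, 200, 500, 1000, 2000]
  repeats: 3
  tests: 5
  seed: 1

readout_permutation:
  env: lorenz
  repeats: 30
  seed: 1

transfer:
  envs: [lorenz, sprottA]
  kappas: [0.0, 0.5, 1.0]
  pops: 2
  pop_size: 20
  gens: 200
  tests: 10
  tests_eval: 25
  seed: 1

topology_compare:
  envs: [lorenz]
  pops: 3
  pop_size: 20
  gens: 200
  tests: 10
  tests_eval: 25
  seed: 1
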
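# Full-scale presets matching the study protocol (cluster-scale: expect
# days of CPU time for the evolutionary experiments).

random_search:
  env: lorenz        # repeat for each of the six environments
  configs: 4000
  tests: 100
  seed: 1

sample_size:
  env: lorenz
  n_grid: !!str "10:2000:10"   # n = 10, 20, ..., 2000
  repeats: 100
  tests: 10
  seed: 1

readout_permutation:
  env: lorenz
  repeats: 100
  seed: 1

transfer:
  envs: [lorenz, sprottA, sprottB, sprottR]
  kappas: [0.0, 0.25, 0.5, 0.75, 1.0]
  pops: 10
  pop_size: 100
  gens: 3000
  tests: 100
  tests_eval: 100
  seed: 1

topology_compare:
  envs: [lorenz, sprottA, sprottB, sprottG, sprottK, sprottR]
  pops: 10
  pop_size: 100
  gens: 3000
  tests: 100
  tests_eval: 100
  seed: 1
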
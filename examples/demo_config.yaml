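# Three-group demonstration run: healthy controls, unilateral
# medial-prefrontal lesion phenotype, and the bilateral strategic-betting
# phenotype.  Run with:
#
#   betbias run --config examples/demo_config.yaml --out out/demo --seed 3
#
seed: 3
n_starts: 5
models: [M1, M2, M4, M5, S1, S2]
task:
  n_trials: 160
  n_blocks: 3
  p_high: 0.7
  p_low: 0.3
cohorts:
  - preset: control
    n_subjects: 6
  - preset: unilateral
    n_subjects: 4
  - preset: bilateral
    n_subjects: 1
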
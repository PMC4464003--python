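analysis:
  class_control: HC
  class_case: AD
  k_folds: 4
  n_ga_models: 60
  ga_generations: 40
  n_bootstrap: 500
  n_random_models: 100
  rng_seed: 7
cohort:
  n_per_class: {HC: 150, AD: 150}
  n_features: 200
  planted:
    - {index: 0, contrast: [HC, AD], delta: 1.5}
    - {index: 1, contrast: [HC, AD], delta: 1.5}
    - {index: 2, contrast: [HC, AD], delta: 1.5}
  n_correlated_pairs: 10
  seed: 7
outdir: scratch/demo_run
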
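# Bundled demo pipeline configuration: a small synthetic survey sample with
# the default (study-condition) generator parameters, sized to run the whole
# pipeline in seconds.
generator:
  n_strata: 8
  clusters_per_stratum: 8
  visits_per_cluster_mean: 2000
  sampling_fraction: 0.2
  seed: 20060101
bootstrap_reps: 400
bootstrap_seed: 11
sim_draws: 1000
sim_seed: 12
risk_scale: 100000
output_dir: pedtrauma_demo_out
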
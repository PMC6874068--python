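# Demo configuration: full synthetic comparison under the default study
# conditions (800 features, four cartridges, two scans).
mode: synthetic
outdir: demo_out
synthetic:
  n_features: 800
  seed: 0
loess:
  span: 0.75
  degree: 2
  grid_points: 100
  trim_fraction: 0.98
clustering:
  metric: euclidean
  method: average
high_expression_percentile: 50
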
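"""Normalize raw lane counts with the three-step control-probe scheme.

Builds RCC-style lane records (with positive, negative and housekeeping
controls and lane-to-lane efficiency differences), then runs positive-control
correction, negative-control background filtering, and housekeeping median
normalization, ending on the log2 scale.
"""

import ncompare as nc

cfg = nc.SyntheticConfig(n_features=300, seed=7)
lanes, truth, efficiency = nc.generate_counts(cfg)
raw = nc.matrix_from_lanes(lanes)
normalized, report = nc.normalize(raw, nc.NormConfig(k_sd=2.0))

print(f"lanes: {raw.n_lanes}, features in: {report.n_features_in}, "
      f"out: {report.n_features_out} ({len(report.removed_features)} below background)")
lane = raw.values.columns[0]
print(f"example lane {lane}: positive factor {report.positive_factor[lane]:.3f}, "
      f"housekeeping factor {report.housekeeping_factor[lane]:.3f}, "
      f"background threshold {report.background_threshold[lane]:.1f} counts")
print("-> factors near 1 mean the lane ran at average efficiency; features that")
print("   never clear mean + 2 SD of the negative controls are treated as noise.")
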
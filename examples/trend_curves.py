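"""LOESS RMS trend curves: how each variance source scales with expression.

Fits the first-scan ANOVA per feature, smooths each source's RMS against
mean log2 expression, and exports the comparable curves (TSV + plot).
"""

import numpy as np

import ncompare as nc

matrix, _ = nc.generate_log2(nc.SyntheticConfig(n_features=800, seed=5))
table = nc.decompose_matrix(matrix, nc.model_spec("scan1"))
curves = nc.curves_for_model(table, span=0.75, degree=2)
paths = nc.export_curves(curves, "trend_scan1")

by_source = {c.source: c for c in curves}
mid = len(curves[0].grid_x) // 2
print(f"wrote {paths['tsv']} and {paths['plot']}")
print("RMS at mid-range expression "
      f"(x = {curves[0].grid_x[mid]:.1f} log2 units):")
for source in ("B", "S", "P", "residual"):
    print(f"  {source:>8}: {by_source[source].smoothed_y[mid]:.3f}")
print("-> biology (B) towers over the instrument terms; prep (P) sits at the")
print("   duplicate-noise floor, scanner (S) slightly above it, and all")
print("   technical curves rise only toward low expression.")
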
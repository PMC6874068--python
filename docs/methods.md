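# Methods

## The comparison design

The framework targets a fixed technical-comparison layout: six biological
samples run in duplicate on each of four 12-lane cartridges, each cartridge
scanned twice. Cartridge A is prepared and scanned on second-generation
instruments, B on first-generation instruments, C mixes a second-generation
PrepStation with a first-generation scanner, and D the reverse. Scanner
generation fixes the fields of view per lane (600 first generation, 320
second). The design yields 96 lane-scan observations per feature and makes
prep, scanner, cartridge, scan-time and biological-sample effects
simultaneously estimable from simple balanced contrasts.

## Normalization

Three conventional control-probe steps, in order, on linear counts:

1. **Positive-control correction.** Per lane, the geometric mean `g_l` of the
   spiked positive probes; factor `mean_l(g)/g_l` rescales every count.
   Corrects lane-to-lane assay efficiency (hybridization, binding, imaging).
2. **Background filtering.** Per lane, threshold `mean + k·SD` of the
   negative probes (sample SD, `k = 2` by default). An endogenous feature is
   kept when it exceeds the lane threshold in at least half the lanes
   (`majority_lanes`; `any_lane` and `all_lanes` are available). Control
   probes are never removed.
3. **Housekeeping median normalization.** Per lane, the median of the
   housekeeping probes; factor `mean_l(median)/median_l`. Finally
   `log2(x + 1)`, so zero counts map to 0.

Thresholds and medians are computed on positive-corrected counts, so each
step sees the previous step's output. The defaults (`k = 2`, majority rule,
offset 1) are the conventional choices for this platform; all are exposed in
`NormConfig`.

A practical caveat worth knowing: when the housekeeping probes' baseline
levels are well separated (several log2 units apart), the lane median always
tracks the same middle probe, so the housekeeping factor inherits that one
probe's full measurement noise rather than a median-of-n reduction. With
five housekeeping probes and residual sd σ, duplicate lanes then disagree
with sd ≈ 2σ rather than √2·σ after normalization. This is a property of
median normalization itself, not of the implementation.

## Per-feature ANOVA

Each feature is fitted independently — effects are feature-specific and the
smoothing happens after fitting, not during. Three fixed-effects models:

| model | observations | terms (df) | residual df |
|---|---|---|---|
| `scan1` | 48 first-scan | P (1), S (1), B (5) | 40 |
| `scan2` | 48 second-scan | PS (2), Cart (1), B (5) | 39 |
| `both_scans` | 48 of A and B, both scans | PS (1), T (1), B (5) | 40 |

The second-scan model codes the combined prep+scanner effect as a 3-level
factor counting second-generation instruments ({A} = 2, {B} = 0,
{C, D} = 1): under additivity C and D share the same prep+scanner sum, so
the only remaining cartridge information is the C-vs-D contrast, coded as a
1-df term nested in the mixed level. This is the unique coding under which
PS, cartridge and sample are simultaneously estimable on this layout.

Sums of squares are sequential in model order and computed from group means
(`SS = Σ n_g (ȳ_g − baseline)²`, with the nested contrast's baseline the
mean of its parent level). On the balanced design all listed terms are
mutually orthogonal, so sequential SS coincide with any classical SS type
and the residual equals the full-model residual driven by within-cartridge
duplicates; the identity `SS_total = Σ SS_terms + SS_residual` is enforced
to 1e-8 relative, and a negative residual beyond that tolerance raises a
confounding error (this catches non-orthogonal custom layouts). Each
source is reported as `RMS = √(SS/df)`, a per-source standard-deviation
scale, together with the feature's mean expression over the model's own
observations.

## LOESS trend curves

Per model, each source's per-feature RMS values are smoothed against mean
log2 expression by classical LOESS: at each evaluation point the
`ceil(span·n)` nearest x-neighbours are fitted with a local polynomial under
tricube weights `(1 − (d/d_max)³)³` and the fit is evaluated at the point.
Defaults span 0.75, degree 2, no robustness iterations. All sources of a
model are evaluated on one common grid — 100 equispaced points over the
central 98% of the mean-expression range (trimming avoids boundary windows
supported by a handful of extreme features) — so curves can be compared
pointwise. Degenerate windows (all x identical) fall back to the weighted
mean; a window with fewer carrying points than the polynomial order falls
back to unweighted fitting.

**Interpretation caveat (small-df bias).** `RMS = √MS` is a chi-distributed
quantity; for a 1-df term under a null effect, `E[RMS] = σ·√(2/π) ≈ 0.80σ`,
while a 40-df residual RMS is nearly unbiased (≈ 0.994σ). A null technical
source's smoothed curve therefore sits systematically ~20% *below* the
residual curve, not on top of it. Curves of same-df sources are directly
comparable; comparisons against the residual curve should keep this bias in
mind (the package's tests assert the biased ratio √(2/π) explicitly). By the
same token the residual curve itself is the cleanest estimate of σ(x).

## Synthetic generator

`generate_log2` draws, per feature g: a baseline μ_g ~ U(1, 14) log2 units
(covering the platform's dynamic range), sample effects b ~ N(0, σ_B²) for
each of the six samples, a prep effect p ~ N(0, σ_P²) added to
second-generation-prep lanes, a scanner effect s ~ N(0, σ_S²) added to
second-generation-scanner lanes, independent per-cartridge effects
c ~ N(0, σ_C²), a scan-time effect t ~ N(0, σ_T²) added at scan 2, and
independent residuals with expression-dependent sd

    σ_E(μ) = a + b·2^(−μ/τ),    defaults a = 0.15, b = 1, τ = 2,

a noise floor that rises at low expression, matching the platform's observed
mean-variance geometry. Effects are drawn once per feature and shared across
that feature's observations — which is exactly what makes per-feature ANOVA
the right estimator. Defaults σ_B = 1, σ_S = 0.1, σ_P = 0.02, σ_C = 0.05,
σ_T = 0.02 reproduce the qualitative regime of a real two-generation
comparison: biology dominant, scanner slightly above duplicate noise, prep
at the noise floor, correlations between matched lanes ≈ 0.99. Generation is
bit-reproducible from (config, seed).

`generate_counts` converts the log2 surface to integer counts
(`round(max(2^y − 1, 0) · eff)`) with lognormal per-physical-lane efficiency
multipliers shared by both scans, and adds a 6-step geometric positive-probe
ladder scaled by the same efficiency, Poisson negatives (mean 8), and five
stable housekeeping probes at 10–13 log2 units. This exercises the
normalization stage end-to-end: positive factors invert the efficiencies and
the normalized matrix correlates > 0.999 per lane with the generating
surface.

What the generator does **not** emulate: count overdispersion beyond Poisson
negatives, probe-specific hybridization efficiencies, cross-hybridization,
ligation-efficiency variation, and cartridge spatial artifacts. Passing
recovery tests therefore validate the statistical machinery on the stated
additive model, not the chemistry of a real run.

`truth_rms` gives exact expectations of every fitted mean square under the
generating model via `E[y'Qy] = tr(QΣ)`, with Q the term's sequential-SS
quadratic form and Σ assembled from the design incidence matrices. On the
default design with σ_C = σ_T = 0 this reduces to the familiar balanced
forms `E[MS_P] = σ² + 12σ_P²`, `E[MS_S] = σ² + 12σ_S²`,
`E[MS_B] = σ² + 8σ_B²`, `E[MS_E] = σ²`. With σ_C > 0 the scan-1 model
absorbs cartridge variation into its terms (P and S each gain 12σ_C²; the
residual gains 0.3σ_C² from the unmodelled third cartridge contrast) — the
trace formula accounts for this exactly, and it is why null-effect recovery
scenarios set σ_C = 0.

## Numerical and design choices

- Matrix round trips are exact: values are written at 17 significant digits
  and parsed with pandas' round-trip float precision.
- Annotated-matrix headers encode lanes as `token_cartridge_scan` with token
  1–12 (1–6 = replicate 1, 7–12 = replicate 2 of samples 1–6); the delimiter
  is configurable.
- Lane pairing for concordance is by (sample, replicate) position;
  correlations are computed on log2 values over all retained features.
- Clustering defaults: Euclidean distance, average linkage, on both
  features and lanes; the heatmap uses a green–black–red map symmetric about
  the matrix median.
- "High expression" in summary ratios = features above the 50th percentile
  of mean expression (configurable).
- Problem sizes in the validation suite: 800 features for geometry and
  recovery checks (matching the assay's panel size), 5000 for Monte-Carlo
  expectation checks; all complete in seconds on one CPU.

## Known limitations

- The three ANOVA models are specific to the 4-cartridge × 2-scan balanced
  layout; unbalanced or partial designs are rejected rather than
  approximated (no REML/mixed-model fallback).
- No interaction terms and no per-feature significance tests are provided —
  inference is by comparing smoothed RMS curves, not p-values.
- The second-scan model's cartridge term is identifiable only as the C-vs-D
  contrast; between-cartridge variance within the pure-generation levels is
  inseparable from the PS effect on this design.
- LOESS curves carry no confidence bands; span/degree are fixed, not
  cross-validated.
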
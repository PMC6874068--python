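"""Synthetic data under the additive per-feature effects model.

The generator emulates the comparison experiment: four 12-lane cartridges
(6 biological samples in duplicate), each prepared on a first- or
second-generation PrepStation, scanned twice on a first- or second-generation
scanner.  For feature *g* and lane-scan observation *l*,

    y_gl = mu_g + b_{g,sample(l)} + p_g [prep(l)=second] + s_g [scanner(l)=second]
           + c_{g,cart(l)} + t_g [scan(l)=2] + eps_gl

with per-feature effect draws b ~ N(0, sigma_B^2), p ~ N(0, sigma_P^2),
s ~ N(0, sigma_S^2), c ~ N(0, sigma_C^2), t ~ N(0, sigma_T^2) shared across
that feature's observations, and independent residuals
eps ~ N(0, sigma_E(mu_g)^2) with an expression-dependent scale

    sigma_E(mu) = noise_a + noise_b * 2**(-mu / noise_tau),

a floor plus a component that rises at low expression, matching the observed
geometry of technical noise on this platform.

A raw-count companion (:func:`generate_counts`) converts the log2 surface to
integer counts with per-lane efficiency multipliers and adds positive,
negative and housekeeping control probes, so the normalization stage can be
exercised end-to-end and inverted.

``truth_rms`` supplies exact expectations of the fitted mean squares under
the generating model via E[y'Qy] = tr(Q Sigma), where Q is the term's
sequential-SS quadratic form and Sigma the covariance induced by the effect
draws; on the default design with sigma_C = sigma_T = 0 this reduces to the
balanced-design formulas E[MS_P] = sigma_e^2 + 12 sigma_P^2,
E[MS_S] = sigma_e^2 + 12 sigma_S^2, E[MS_B] = sigma_e^2 + 8 sigma_B^2,
E[MS_E] = sigma_e^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anova import AnovaModelSpec, model_spec
from .errors import ConfigurationError, DesignError, NCompareError
from .io import (
    CodeClass,
    DesignSpec,
    ExpressionMatrix,
    LANE_ANNOTATION_COLUMNS,
    LaneRecord,
    ProbeRecord,
    build_design,
    lane_column_id,
)

__all__ = [
    "ControlSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_log2",
    "generate_counts",
    "truth_rms",
]


@dataclass(frozen=True)
class ControlSpec:
    """Control-probe layout for the raw-count generator.

    Positives follow a geometric ladder (top count divided by ``positive_ratio``
    at each step) scaled by the lane efficiency; negatives are Poisson draws
    around ``negative_mean``; housekeeping probes are stable high expressors
    with per-probe baselines drawn uniformly on
    [housekeeping_low, housekeeping_high] (log2 units).
    """

    n_positive: int = 6
    positive_top: float = 8192.0
    positive_ratio: float = 4.0
    n_negative: int = 8
    negative_mean: float = 8.0
    n_housekeeping: int = 5
    housekeeping_low: float = 10.0
    housekeeping_high: float = 13.0
    lane_efficiency_sd: float = 0.1
    count_log_offset: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the comparison experiment: 800 endogenous features on the
    default four-cartridge design; biological spread dominating
    (sigma_B = 1 log2 unit), a small scanner effect (0.1), a near-null
    PrepStation effect (0.02), modest cartridge and scan-time effects, and a
    residual noise floor of 0.15 log2 units rising at low expression.
    """

    n_features: int = 800
    design: DesignSpec = field(default_factory=build_design)
    sigma_B: float = 1.0
    sigma_P: float = 0.02
    sigma_S: float = 0.1
    sigma_C: float = 0.05
    sigma_T: float = 0.02
    noise_a: float = 0.15
    noise_b: float = 1.0
    noise_tau: float = 2.0
    baseline_low: float = 1.0
    baseline_high: float = 14.0
    seed: int = 0
    control_spec: ControlSpec = field(default_factory=ControlSpec)

    def __post_init__(self) -> None:
        for name in ("sigma_B", "sigma_P", "sigma_S", "sigma_C", "sigma_T"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_a <= 0:
            raise ConfigurationError("noise_a must be > 0 (residual sd floor)")
        if self.baseline_low >= self.baseline_high:
            raise ConfigurationError("baseline_low must be < baseline_high")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        lo = self.noise_sd(np.array([self.baseline_low, self.baseline_high]))
        if (lo <= 0).any():
            raise ConfigurationError("sigma_E(mu) must stay positive over the baseline range")

    def noise_sd(self, mu: np.ndarray) -> np.ndarray:
        """Residual sd at log2 expression level ``mu``."""
        return self.noise_a + self.noise_b * np.power(2.0, -np.asarray(mu, dtype=float) / self.noise_tau)

    def with_(self, **kwargs) -> "SyntheticConfig":
        """Copy with fields replaced (convenience for scenario definitions)."""
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Generating draws behind one synthetic matrix (for recovery tests)."""

    baselines: pd.Series                 # per-feature mu_g
    sample_effects: pd.DataFrame         # features x 6 samples
    prep_effects: pd.Series              # p_g, applied when prep = second
    scanner_effects: pd.Series           # s_g, applied when scanner = second
    cartridge_effects: pd.DataFrame      # features x cartridges
    scan_effects: pd.Series              # t_g, applied at scan 2
    config: SyntheticConfig

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "baselines": self.baselines.to_frame("mu"),
            "sample_effects": self.sample_effects,
            "prep_effects": self.prep_effects.to_frame("p"),
            "scanner_effects": self.scanner_effects.to_frame("s"),
            "cartridge_effects": self.cartridge_effects,
            "scan_effects": self.scan_effects.to_frame("t"),
        }


def _feature_names(n: int) -> pd.Index:
    return pd.Index([f"synth-miR-{i:04d}" for i in range(1, n + 1)], name="feature")


def generate_log2(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a log2 expression matrix plus the generating truth.

    Deterministic: the same ``(config, seed)`` yields a bit-identical matrix.
    All features are annotated ``Endogenous`` (controls only exist on the
    count scale; the log2 surface is what the models see after normalization).
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    cartridges = design.cartridges
    n = config.n_features
    features = _feature_names(n)

    mu = rng.uniform(config.baseline_low, config.baseline_high, size=n)
    b = rng.normal(0.0, config.sigma_B, size=(n, 6))
    p = rng.normal(0.0, config.sigma_P, size=n)
    s = rng.normal(0.0, config.sigma_S, size=n)
    c = rng.normal(0.0, config.sigma_C, size=(n, len(cartridges)))
    t = rng.normal(0.0, config.sigma_T, size=n)
    sigma_e = config.noise_sd(mu)

    cart_index = {cart: i for i, cart in enumerate(cartridges)}
    cols = {}
    ann_rows = []
    for cart, scan, sample, rep in design.lanes:
        y = mu + b[:, sample - 1] + c[:, cart_index[cart]]
        if design.prep_generation[cart] == "second":
            y = y + p
        if design.scanner_generation[cart] == "second":
            y = y + s
        if scan == 2:
            y = y + t
        y = y + rng.normal(0.0, 1.0, size=n) * sigma_e
        col = lane_column_id(cart, scan, sample, rep)
        cols[col] = y
        ann_rows.append((col, cart, scan, sample, rep))

    values = pd.DataFrame(cols, index=features)
    lane_ann = pd.DataFrame(
        [r[1:] for r in ann_rows],
        index=pd.Index([r[0] for r in ann_rows], name="lane"),
        columns=list(LANE_ANNOTATION_COLUMNS),
    )
    feat_ann = pd.Series(CodeClass.ENDOGENOUS, index=features, name="code_class")
    matrix = ExpressionMatrix(values, "log2", feat_ann, lane_ann)
    truth = SyntheticTruth(
        baselines=pd.Series(mu, index=features, name="mu"),
        sample_effects=pd.DataFrame(b, index=features, columns=[f"sample_{i}" for i in range(1, 7)]),
        prep_effects=pd.Series(p, index=features, name="p"),
        scanner_effects=pd.Series(s, index=features, name="s"),
        cartridge_effects=pd.DataFrame(c, index=features, columns=cartridges),
        scan_effects=pd.Series(t, index=features, name="t"),
        config=config,
    )
    return matrix, truth


def generate_counts(
    config: SyntheticConfig,
) -> tuple[list[LaneRecord], SyntheticTruth, pd.Series]:
    """Raw-count companion of :func:`generate_log2`.

    Endogenous counts are ``round(max(2^y - offset, 0) * eff_lane)`` where the
    per-physical-lane efficiency multiplier ``eff`` (shared by both scans of a
    lane) is lognormal around 1.  Positive probes follow the geometric ladder
    scaled by the same efficiency; negatives are Poisson; housekeeping probes
    are stable high expressors.  Returns the lane records, the generating
    truth, and the per-lane efficiencies (indexed by physical lane id).
    """
    cs = config.control_spec
    matrix, truth = generate_log2(config)
    # independent stream for count-level randomness, offset so it never
    # collides with the expression stream
    rng = np.random.default_rng((config.seed + 1_000_003) % (2**31))
    design = config.design

    phys = sorted({(cart, sample, rep) for cart, _, sample, rep in design.lanes})
    eff = pd.Series(
        np.exp(rng.normal(0.0, cs.lane_efficiency_sd, size=len(phys))),
        index=pd.Index([f"{c}-{s}-{r}" for c, s, r in phys]),
        name="efficiency",
    )
    eff_map = dict(zip(phys, eff.to_numpy()))

    ladder = cs.positive_top / cs.positive_ratio ** np.arange(cs.n_positive)
    hk_mu = rng.uniform(cs.housekeeping_low, cs.housekeeping_high, size=cs.n_housekeeping)

    lanes: list[LaneRecord] = []
    for cart, scan, sample, rep in design.lanes:
        e = eff_map[(cart, sample, rep)]
        col = lane_column_id(cart, scan, sample, rep)
        y = matrix.values[col].to_numpy()
        endo = np.rint(np.maximum(np.power(2.0, y) - cs.count_log_offset, 0.0) * e).astype(int)

        probes = [
            ProbeRecord(CodeClass.POSITIVE, f"POS_{chr(65 + i)}", f"POS_{chr(65 + i)}",
                        int(round(ladder[i] * e)))
            for i in range(cs.n_positive)
        ]
        probes += [
            ProbeRecord(CodeClass.NEGATIVE, f"NEG_{chr(65 + i)}", f"NEG_{chr(65 + i)}",
                        int(rng.poisson(cs.negative_mean)))
            for i in range(cs.n_negative)
        ]
        hk_vals = hk_mu + rng.normal(0.0, config.noise_a, size=cs.n_housekeeping)
        probes += [
            ProbeRecord(CodeClass.HOUSEKEEPING, f"HK_{i + 1}", f"HK_{i + 1}",
                        int(round(float(np.power(2.0, hk_vals[i])) * e)))
            for i in range(cs.n_housekeeping)
        ]
        probes += [
            ProbeRecord(CodeClass.ENDOGENOUS, name, name, int(count))
            for name, count in zip(matrix.values.index, endo)
        ]
        lanes.append(
            LaneRecord(
                lane_id=f"{cart}-{sample}.{rep}-scan{scan}",
                cartridge=cart,
                scan_index=scan,
                sample_number=sample,
                replicate=rep,
                fov_count=design.fov_count(cart),
                probes=probes,
            )
        )
    return lanes, truth, eff


# ---------------------------------------------------------------------------
# Analytic expectations of fitted mean squares
# ---------------------------------------------------------------------------

def _is_default_design(design: DesignSpec) -> bool:
    ref = build_design()
    return (
        design.prep_generation == ref.prep_generation
        and design.scanner_generation == ref.scanner_generation
        and sorted(design.lanes) == sorted(ref.lanes)
    )


def _term_quadratic_form(labels: pd.Series, n: int) -> np.ndarray:
    """Matrix Q with SS_term = y'Qy for a (possibly nested) group-means term."""
    mask = labels.notna().to_numpy()
    idx = np.where(mask)[0]
    codes, uniques = pd.factorize(labels[labels.notna()], sort=True)
    Q = np.zeros((n, n))
    for g in range(len(uniques)):
        members = idx[codes == g]
        Q[np.ix_(members, members)] += 1.0 / len(members)
    Q[np.ix_(idx, idx)] -= 1.0 / len(idx)
    return Q


def truth_rms(config: SyntheticConfig, model_id: str,
              sigma_eps: float | None = None) -> pd.DataFrame:
    """Exact expected MS and RMS per source under the generating model.

    ``sigma_eps`` fixes the residual sd; by default it is evaluated at the
    midpoint of the baseline range (with expression-dependent noise the
    fitted mean squares averaged over features correspond to the average of
    ``sigma_E(mu)^2`` instead — pass an explicit value for exact comparisons).
    Only the default design is supported.
    """
    if not _is_default_design(config.design):
        raise DesignError("truth_rms supports only the default four-cartridge design")
    spec: AnovaModelSpec = model_spec(model_id, config.design)

    lanes = [lane for lane in config.design.lanes]
    ann = pd.DataFrame(lanes, columns=list(LANE_ANNOTATION_COLUMNS))
    mask = spec.obs_filter(ann)
    ann = ann[mask].reset_index(drop=True)
    n = len(ann)
    if n != spec.expected_n:
        raise NCompareError("internal error: observation filter mismatch")

    if sigma_eps is None:
        sigma_eps = float(config.noise_sd((config.baseline_low + config.baseline_high) / 2.0))

    # covariance of one feature's observation vector induced by the draws
    design = config.design
    Z_b = pd.get_dummies(ann["sample_number"]).to_numpy(dtype=float)
    z_p = (ann["cartridge"].map(design.prep_generation) == "second").to_numpy(dtype=float)
    z_s = (ann["cartridge"].map(design.scanner_generation) == "second").to_numpy(dtype=float)
    Z_c = pd.get_dummies(ann["cartridge"]).to_numpy(dtype=float)
    z_t = (ann["scan_index"] == 2).to_numpy(dtype=float)
    sigma = (
        config.sigma_B**2 * Z_b @ Z_b.T
        + config.sigma_P**2 * np.outer(z_p, z_p)
        + config.sigma_S**2 * np.outer(z_s, z_s)
        + config.sigma_C**2 * Z_c @ Z_c.T
        + config.sigma_T**2 * np.outer(z_t, z_t)
        + sigma_eps**2 * np.eye(n)
    )

    qforms = {}
    for term in spec.terms:
        qforms[term.name] = _term_quadratic_form(term.label_fn(ann, design), n)
    grand = np.full((n, n), 1.0 / n)
    q_resid = np.eye(n) - grand - sum(qforms.values())
    qforms["residual"] = q_resid

    dfs = {t.name: t.df for t in spec.terms}
    dfs["residual"] = spec.residual_df
    rows = []
    for source in spec.sources:
        ems = float(np.trace(qforms[source] @ sigma)) / dfs[source]
        rows.append((source, dfs[source], ems, np.sqrt(ems)))
    return pd.DataFrame(rows, columns=["source", "df", "expected_ms", "expected_rms"]).set_index("source")
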
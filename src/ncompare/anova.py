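"""Per-feature ANOVA variance decomposition on the four-cartridge design.

Three fixed-effects models partition the variability of each feature's log2
expression, one model per comparison:

``scan1``
    First-scan observations of all four cartridges (48 obs):
    prep generation **P** (1 df), scanner generation **S** (1 df), biological
    sample **B** (5 df), residual (40 df).  P and S are identified because the
    cartridges realize all four prep x scanner combinations.
``scan2``
    Second-scan observations (48 obs): the combined prep+scanner effect
    **PS** as a 3-level factor counting second-generation instruments
    ({A}=2, {B}=0, {C,D}=1; 2 df), the between-cartridge contrast **Cart**
    (C vs D nested in the mixed PS level, 1 df), sample **B** (5 df),
    residual (39 df).  Under additivity C and D share the same prep+scanner
    sum, so only their cartridge difference remains estimable.
``both_scans``
    Cartridges A and B at both scans (48 obs): **PS** (A vs B, 1 df), scan
    time **T** (1 df), sample **B** (5 df), residual (40 df).

Sums of squares are sequential in model order, computed from group means;
on the balanced design all listed terms are mutually orthogonal, so they
coincide with any classical SS type and the residual equals the full-model
residual (within-cartridge duplicates).  The per-source scale reported is
RMS = sqrt(MS), comparable across sources and smoothable against expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignMismatchError, NCompareError
from .io import DesignSpec, ExpressionMatrix, build_design

MODEL_IDS = ("scan1", "scan2", "both_scans")

#: Relative tolerance for the SS conservation identity on balanced designs.
_CONSERVATION_RTOL = 1e-8


@dataclass(frozen=True)
class TermDef:
    """One model term.

    ``label_fn`` maps the lane-annotation frame to per-observation level
    labels; observations labelled ``None`` do not participate in the term
    (used for contrasts nested inside one level of a parent factor, whose
    baseline is then the mean of the participating observations).
    """

    name: str
    df: int
    label_fn: Callable[[pd.DataFrame, DesignSpec], pd.Series]


@dataclass
class AnovaModelSpec:
    model_id: str
    terms: list[TermDef]
    obs_filter: Callable[[pd.DataFrame], pd.Series]
    expected_n: int
    design: DesignSpec

    @property
    def residual_df(self) -> int:
        return self.expected_n - 1 - sum(t.df for t in self.terms)

    @property
    def sources(self) -> list[str]:
        return [t.name for t in self.terms] + ["residual"]


def _second_count(ann: pd.DataFrame, design: DesignSpec) -> pd.Series:
    prep = ann["cartridge"].map(design.prep_generation)
    scan = ann["cartridge"].map(design.scanner_generation)
    return ((prep == "second").astype(int) + (scan == "second").astype(int)).astype(str)


def model_spec(model_id: str, design: DesignSpec | None = None) -> AnovaModelSpec:
    """Build the :class:`AnovaModelSpec` for one of the three comparisons."""
    design = design or build_design()
    if model_id == "scan1":
        terms = [
            TermDef("P", 1, lambda a, d: a["cartridge"].map(d.prep_generation)),
            TermDef("S", 1, lambda a, d: a["cartridge"].map(d.scanner_generation)),
            TermDef("B", 5, lambda a, d: a["sample_number"].astype(str)),
        ]
        return AnovaModelSpec(model_id, terms, lambda a: a["scan_index"] == 1, 48, design)
    if model_id == "scan2":
        def cart_contrast(a: pd.DataFrame, d: DesignSpec) -> pd.Series:
            mixed = _second_count(a, d) == "1"
            labels = a["cartridge"].where(mixed, other=None)
            return labels

        terms = [
            TermDef("PS", 2, _second_count),
            TermDef("Cart", 1, cart_contrast),
            TermDef("B", 5, lambda a, d: a["sample_number"].astype(str)),
        ]
        return AnovaModelSpec(model_id, terms, lambda a: a["scan_index"] == 2, 48, design)
    if model_id == "both_scans":
        terms = [
            TermDef("PS", 1, _second_count),
            TermDef("T", 1, lambda a, d: a["scan_index"].astype(str)),
            TermDef("B", 5, lambda a, d: a["sample_number"].astype(str)),
        ]
        return AnovaModelSpec(
            model_id, terms, lambda a: a["cartridge"].isin(["A", "B"]), 48, design
        )
    raise NCompareError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")


def _term_ss(Y: np.ndarray, labels: pd.Series, term: TermDef) -> np.ndarray:
    """Sequential SS of one term for every feature (rows of ``Y``).

    For a fully-labelled factor this is the classical between-group SS
    ``sum_g n_g (mean_g - grand)^2``; for a nested contrast the baseline is
    the mean over the labelled subset only.
    """
    mask = labels.notna().to_numpy()
    sub = Y[:, mask]
    lab = labels[labels.notna()]
    codes, uniques = pd.factorize(lab, sort=True)
    n_levels = len(uniques)
    if n_levels != term.df + 1:
        raise DesignMismatchError(
            f"term {term.name}: expected {term.df + 1} levels, observed {n_levels} "
            f"({list(uniques)})"
        )
    Z = np.zeros((sub.shape[1], n_levels))
    Z[np.arange(sub.shape[1]), codes] = 1.0
    counts = Z.sum(axis=0)
    group_means = (sub @ Z) / counts
    baseline = sub.mean(axis=1, keepdims=True)
    dev = group_means - baseline
    return (dev**2 * counts).sum(axis=1)


def _decompose_values(Y: np.ndarray, annotations: pd.DataFrame,
                      spec: AnovaModelSpec) -> dict[str, np.ndarray]:
    """SS per source for a (features x observations) block already filtered."""
    n = Y.shape[1]
    if n != spec.expected_n:
        raise DesignMismatchError(
            f"model {spec.model_id} expects {spec.expected_n} observations, got {n}"
        )
    total = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss = {}
    for term in spec.terms:
        labels = term.label_fn(annotations, spec.design)
        ss[term.name] = _term_ss(Y, labels, term)
    resid = total - sum(ss.values())
    scale = np.maximum(total, 1.0)
    if (resid < -_CONSERVATION_RTOL * scale).any():
        raise DesignMismatchError(
            f"model {spec.model_id}: negative residual SS — model terms are not "
            "orthogonal on this observation layout (confounded terms)"
        )
    ss["residual"] = np.maximum(resid, 0.0)
    return ss


@dataclass
class FeatureAnova:
    """df / SS / MS / RMS per source for one feature, plus its mean expression."""

    feature: str
    mean_expression: float
    table: pd.DataFrame  # index: sources; columns: df, ss, ms, rms

    def ss(self, source: str) -> float:
        return float(self.table.loc[source, "ss"])

    def rms(self, source: str) -> float:
        return float(self.table.loc[source, "rms"])


def fit_feature_anova(values: Sequence[float], annotations: pd.DataFrame,
                      spec: AnovaModelSpec, feature: str = "feature") -> FeatureAnova:
    """Fit one model to a single feature's observations.

    ``values`` and ``annotations`` must already be restricted to the model's
    observations (48 on the default design) and aligned row-for-row.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise DesignMismatchError("values must be one-dimensional")
    if np.isnan(y).any():
        raise DesignMismatchError("missing values in observations")
    ss = _decompose_values(y[None, :], annotations.reset_index(drop=True), spec)
    dfs = {t.name: t.df for t in spec.terms}
    dfs["residual"] = spec.residual_df
    rows = []
    for source in spec.sources:
        s = float(ss[source][0])
        d = dfs[source]
        ms = s / d
        rows.append((source, d, s, ms, np.sqrt(ms)))
    table = pd.DataFrame(rows, columns=["source", "df", "ss", "ms", "rms"]).set_index("source")
    return FeatureAnova(feature=feature, mean_expression=float(y.mean()), table=table)


def decompose_matrix(matrix: ExpressionMatrix, spec: AnovaModelSpec) -> pd.DataFrame:
    """Fit the model independently to every feature of a log2 matrix.

    Returns a tidy frame with one row per feature: ``mean_expression`` over
    the model's observations, then ``df_X / ss_X / ms_X / rms_X`` for every
    source X (model terms plus ``residual``).
    """
    if matrix.n_features == 0:
        raise NCompareError("empty matrix: no features to decompose")
    ann = matrix.lane_annotations
    mask = spec.obs_filter(ann).to_numpy()
    cols = list(ann.index[mask])
    sub_ann = ann.loc[cols].reset_index(drop=True)
    Y = matrix.values[cols].to_numpy(dtype=float)
    ss = _decompose_values(Y, sub_ann, spec)
    dfs = {t.name: t.df for t in spec.terms}
    dfs["residual"] = spec.residual_df
    out = pd.DataFrame(index=matrix.values.index.copy())
    out["mean_expression"] = Y.mean(axis=1)
    for source in spec.sources:
        ms = ss[source] / dfs[source]
        out[f"df_{source}"] = dfs[source]
        out[f"ss_{source}"] = ss[source]
        out[f"ms_{source}"] = ms
        out[f"rms_{source}"] = np.sqrt(ms)
    return out


def anova_sources(table: pd.DataFrame) -> list[str]:
    """Source names present in a :func:`decompose_matrix` table, model order."""
    return [c[len("rms_"):] for c in table.columns if c.startswith("rms_")]
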
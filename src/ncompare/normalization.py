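"""Three-step nCounter normalization with log2 transform.

The pipeline follows the conventional control-probe scheme:

1. **Positive-control efficiency correction** — each lane is scaled so its
   geometric mean of spiked positive probes matches the across-lane average,
   absorbing lane-to-lane differences in assay efficiency.
2. **Negative-control background filtering** — per lane, a background
   threshold of ``mean + k_sd * sd`` of the negative probes; endogenous
   features that fail to exceed it in enough lanes are dropped.
3. **Housekeeping median normalization** — each lane is scaled so the median
   of its housekeeping probes matches the across-lane average of lane medians.

Finally values are transformed as ``log2(x + log_offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NCompareError
from .io import CodeClass, ExpressionMatrix

BACKGROUND_RULES = ("majority_lanes", "any_lane", "all_lanes")


@dataclass
class NormConfig:
    """Tunables of the normalization pipeline.

    k_sd
        Multiplier of the negative-control standard deviation in the
        background threshold (mean + k_sd * sd).  Default 2, the conventional
        nCounter background definition.
    log_offset
        Pseudo-count added before log2 so zero counts map to 0.
    background_rule
        Which lanes must exceed the threshold for an endogenous feature to be
        kept: at least half (``majority_lanes``), any one (``any_lane``), or
        every lane (``all_lanes``).
    """

    k_sd: float = 2.0
    log_offset: float = 1.0
    background_rule: str = "majority_lanes"

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ConfigurationError(f"k_sd must be >= 0, got {self.k_sd}")
        if self.log_offset < 0:
            raise ConfigurationError(f"log_offset must be >= 0, got {self.log_offset}")
        if self.background_rule not in BACKGROUND_RULES:
            raise ConfigurationError(
                f"background_rule must be one of {BACKGROUND_RULES}, got {self.background_rule!r}"
            )


@dataclass
class NormalizationReport:
    """Per-lane factors/thresholds and the list of features removed."""

    positive_factor: pd.Series
    housekeeping_factor: pd.Series
    background_threshold: pd.Series
    removed_features: list[str] = field(default_factory=list)
    n_features_in: int = 0
    n_features_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "positive_factor": self.positive_factor,
                "housekeeping_factor": self.housekeeping_factor,
                "background_threshold": self.background_threshold,
            }
        )


def _class_block(matrix: ExpressionMatrix, code_class: CodeClass, min_rows: int,
                 what: str) -> pd.DataFrame:
    rows = matrix.features_of_class(code_class)
    if len(rows) < min_rows:
        raise ConfigurationError(
            f"normalization requires >= {min_rows} {what} probe(s); found {len(rows)}"
        )
    return matrix.values.loc[rows]


def positive_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Per-lane efficiency factors from positive-control geometric means.

    With ``g_l`` the geometric mean of positive counts in lane ``l``, the
    factor is ``mean_l(g) / g_l``, so scaled lane geomeans are constant.
    """
    block = _class_block(matrix, CodeClass.POSITIVE, 1, "Positive")
    if (block.to_numpy() <= 0).any():
        raise NCompareError("positive-control count of 0: geometric mean undefined")
    geomeans = np.exp(np.log(block).mean(axis=0))
    factors = geomeans.mean() / geomeans
    factors.name = "positive_factor"
    return factors


def background_thresholds(matrix: ExpressionMatrix, k_sd: float = 2.0) -> pd.Series:
    """Per-lane background as mean + k_sd * sample-sd of negative controls."""
    block = _class_block(matrix, CodeClass.NEGATIVE, 2, "Negative")
    thresholds = block.mean(axis=0) + k_sd * block.std(axis=0, ddof=1)
    thresholds.name = "background_threshold"
    return thresholds


def filter_background(matrix: ExpressionMatrix, thresholds: pd.Series,
                      rule: str = "majority_lanes") -> tuple[ExpressionMatrix, list[str]]:
    """Drop endogenous features at noise level; control probes always stay.

    A feature counts as detected in a lane when its value strictly exceeds
    that lane's threshold.  Returns the filtered matrix (feature order
    preserved) and the removed feature names.
    """
    if rule not in BACKGROUND_RULES:
        raise ConfigurationError(f"unknown background rule {rule!r}")
    missing = [c for c in matrix.values.columns if c not in thresholds.index]
    if missing:
        raise ConfigurationError(f"no background threshold for lanes {missing}")
    above = matrix.values.gt(thresholds[matrix.values.columns], axis=1)
    frac = above.mean(axis=1)
    if rule == "majority_lanes":
        keep_feature = frac >= 0.5
    elif rule == "any_lane":
        keep_feature = frac > 0
    else:  # all_lanes
        keep_feature = frac >= 1.0
    is_endogenous = matrix.feature_annotations == CodeClass.ENDOGENOUS
    keep = keep_feature | ~is_endogenous
    removed = list(matrix.values.index[~keep])
    return matrix.subset_features(matrix.values.index[keep]), removed


def housekeeping_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Per-lane factors from housekeeping medians: ``mean_l(median) / median_l``."""
    block = _class_block(matrix, CodeClass.HOUSEKEEPING, 1, "Housekeeping")
    medians = block.median(axis=0)
    if (medians <= 0).any():
        raise NCompareError("housekeeping median of 0 in some lane; factor undefined")
    factors = medians.mean() / medians
    factors.name = "housekeeping_factor"
    return factors


def normalize(matrix: ExpressionMatrix,
              config: NormConfig | None = None) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Full pipeline: positive correction -> background filter -> housekeeping -> log2.

    Background thresholds and housekeeping medians are computed on the
    positive-corrected counts, so each step sees the output of the previous
    one.  Returns the log2 matrix plus a report of factors, thresholds and
    removed features.
    """
    if matrix.scale != "linear_counts":
        raise ConfigurationError("normalize expects a linear-count matrix")
    config = config or NormConfig()

    pos = positive_factors(matrix)
    corrected = ExpressionMatrix(
        matrix.values.mul(pos, axis=1),
        "linear_counts",
        matrix.feature_annotations.copy(),
        matrix.lane_annotations.copy(),
    )

    thresholds = background_thresholds(corrected, config.k_sd)
    filtered, removed = filter_background(corrected, thresholds, config.background_rule)

    hk = housekeeping_factors(filtered)
    scaled = filtered.values.mul(hk, axis=1)

    log2 = ExpressionMatrix(
        np.log2(scaled + config.log_offset),
        "log2",
        filtered.feature_annotations.copy(),
        filtered.lane_annotations.copy(),
    )
    report = NormalizationReport(
        positive_factor=pos,
        housekeeping_factor=hk,
        background_threshold=thresholds,
        removed_features=removed,
        n_features_in=matrix.n_features,
        n_features_out=log2.n_features,
    )
    return log2, report
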
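import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ncompare as nc
from ncompare.io import CodeClass, ExpressionMatrix, LANE_ANNOTATION_COLUMNS

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_matrix():
    """A 200-feature synthetic log2 matrix on the full design, default sigmas."""
    matrix, truth = nc.generate_log2(nc.SyntheticConfig(n_features=200, seed=7))
    return matrix, truth


def make_matrix(values: dict, feature_classes: list, annotations: list,
                scale: str = "linear_counts") -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from plain dicts/lists (test helper).

    ``values``: {column_id: list of per-feature values}; ``annotations``:
    one (cartridge, scan, sample, replicate) tuple per column.
    """
    df = pd.DataFrame(values, dtype=float)
    df.index = pd.Index([f"f{i}" for i in range(len(df))] if isinstance(feature_classes, int)
                        else [name for name, _ in feature_classes], name="feature")
    classes = pd.Series([cls for _, cls in feature_classes], index=df.index, name="code_class")
    lane_ann = pd.DataFrame(annotations, index=pd.Index(df.columns, name="lane"),
                            columns=list(LANE_ANNOTATION_COLUMNS))
    return ExpressionMatrix(df, scale, classes, lane_ann)


@pytest.fixture()
def two_lane_toy():
    """Two-lane toy with hand-computable normalization factors.

    Lane 1 positive geomean 100, lane 2 positive geomean 200; negatives
    {10,12,14} in both; housekeeping counts 100 and 400.
    """
    return make_matrix(
        values={
            "1_A_1": [50, 200, 10, 12, 14, 100, 500, 10],
            "1_B_1": [100, 400, 10, 12, 14, 400, 1000, 12],
        },
        feature_classes=[
            ("POS_A", CodeClass.POSITIVE),
            ("POS_B", CodeClass.POSITIVE),
            ("NEG_A", CodeClass.NEGATIVE),
            ("NEG_B", CodeClass.NEGATIVE),
            ("NEG_C", CodeClass.NEGATIVE),
            ("HK_1", CodeClass.HOUSEKEEPING),
            ("miR-high", CodeClass.ENDOGENOUS),
            ("miR-low", CodeClass.ENDOGENOUS),
        ],
        annotations=[("A", 1, 1, 1), ("B", 1, 1, 1)],
    )


@pytest.fixture(scope="session")
def scan1_annotations():
    """Lane-annotation frame for the 48 first-scan observations."""
    design = nc.build_design()
    rows = [lane for lane in design.lanes if lane[1] == 1]
    return pd.DataFrame(rows, columns=list(LANE_ANNOTATION_COLUMNS))
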
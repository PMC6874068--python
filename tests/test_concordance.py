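"""Lane concordance, correlation properties, clustering geometry."""

import numpy as np
import pandas as pd
import pytest

import ncompare as nc
from ncompare.concordance import column_partition
from ncompare.errors import NCompareError, PairingError, UndefinedStatisticError
from ncompare.io import CodeClass
from conftest import make_matrix


def _two_column_matrix(col_a, col_b):
    return make_matrix(
        {"1_A_1": col_a, "1_B_1": col_b},
        [(f"miR-{i}", CodeClass.ENDOGENOUS) for i in range(len(col_a))],
        [("A", 1, 1, 1), ("B", 1, 1, 1)],
        scale="log2",
    )


class TestPairwisePcc:
    def test_identical_lane_gives_unit_pcc(self):
        m = _two_column_matrix([1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 5.0])
        table = nc.pairwise_pcc(m, ("A", "B"), 1)
        assert table["pcc"].to_list() == pytest.approx([1.0])

    def test_reversed_lane_gives_minus_one(self):
        m = _two_column_matrix([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        table = nc.pairwise_pcc(m, ("A", "B"), 1)
        assert table["pcc"].to_list() == pytest.approx([-1.0])

    def test_full_design_has_twelve_rows(self, default_matrix):
        matrix, _ = default_matrix
        for pair in (("A", "B"), ("C", "D")):
            table = nc.pairwise_pcc(matrix, pair, 1)
            assert len(table) == 12
            assert table["n_features"].eq(matrix.n_features).all()
            assert table["pcc"].between(-1, 1).all()

    def test_symmetric_in_pair_order(self, default_matrix):
        matrix, _ = default_matrix
        ab = nc.pairwise_pcc(matrix, ("A", "B"), 1)["pcc"]
        ba = nc.pairwise_pcc(matrix, ("B", "A"), 1)["pcc"]
        assert np.allclose(ab, ba)

    def test_affine_invariance_positive_slope(self, default_matrix):
        matrix, _ = default_matrix
        before = nc.pairwise_pcc(matrix, ("A", "B"), 1)["pcc"].to_numpy()
        transformed = matrix.values.copy()
        cols = matrix.lanes_where(cartridge="A", scan_index=1)
        transformed[cols] = transformed[cols] * 3.0 + 2.0
        m2 = nc.ExpressionMatrix(transformed, "log2",
                                 matrix.feature_annotations.copy(),
                                 matrix.lane_annotations.copy())
        after = nc.pairwise_pcc(m2, ("A", "B"), 1)["pcc"].to_numpy()
        assert np.allclose(before, after)

    def test_missing_lane_is_pairing_error(self, default_matrix):
        matrix, _ = default_matrix
        keep = [c for c in matrix.values.columns if c != "1_B_1"]
        m2 = nc.ExpressionMatrix(matrix.values[keep], "log2",
                                 matrix.feature_annotations.copy(),
                                 matrix.lane_annotations.loc[keep].copy())
        with pytest.raises(PairingError, match="cartridge B"):
            nc.pairwise_pcc(m2, ("A", "B"), 1)

    def test_zero_variance_lane_is_undefined(self):
        m = _two_column_matrix([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            nc.pairwise_pcc(m, ("A", "B"), 1)


class TestScanpairPcc:
    def test_identical_scans_give_unit_pcc(self):
        m = make_matrix(
            {"1_A_1": [1.0, 4.0, 9.0], "1_A_2": [1.0, 4.0, 9.0]},
            [(f"miR-{i}", CodeClass.ENDOGENOUS) for i in range(3)],
            [("A", 1, 1, 1), ("A", 2, 1, 1)],
            scale="log2",
        )
        table = nc.scanpair_pcc(m, "A")
        assert table["pcc"].to_list() == pytest.approx([1.0])

    def test_near_identical_scans_on_synthetic(self):
        cfg = nc.SyntheticConfig(n_features=300, seed=31, sigma_T=0.0,
                                 noise_a=0.05, noise_b=0.2)
        m, _ = nc.generate_log2(cfg)
        for cart in "AB":
            table = nc.scanpair_pcc(m, cart)
            assert len(table) == 12
            assert (table["pcc"] > 0.99).all()


class TestPccRange:
    def test_single_row(self):
        table = pd.DataFrame({"pcc": [0.5]})
        assert nc.pcc_range(table) == (0.5, 0.5)

    def test_extrema(self):
        table = pd.DataFrame({"pcc": [0.2, 0.9, 0.4]})
        assert nc.pcc_range(table) == (0.2, 0.9)

    def test_empty_table_errors(self):
        with pytest.raises(NCompareError):
            nc.pcc_range(pd.DataFrame({"pcc": []}))


class TestClusterHeatmap:
    def test_separated_groups_split_at_top(self):
        """Columns from two groups 4 log2 units apart split into the groups."""
        rng = np.random.default_rng(55)
        base = rng.uniform(2, 12, size=40)
        cols, ann = {}, []
        for i in range(6):
            sample = i + 1
            shift = 4.0 if i >= 3 else 0.0
            cols[f"{sample}_A_1"] = base + shift + rng.normal(0, 0.1, size=40)
            ann.append(("A", 1, sample, 1))
        m = make_matrix(cols, [(f"miR-{i}", CodeClass.ENDOGENOUS) for i in range(40)],
                        ann, scale="log2")
        labels = column_partition(m, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_replicates_are_mutual_nearest_neighbours(self):
        """Duplicate lanes of each sample cluster together at default noise."""
        cfg = nc.SyntheticConfig(n_features=300, seed=32)
        m, _ = nc.generate_log2(cfg)
        cols = m.lanes_where(cartridge="A", scan_index=1)
        sub = nc.ExpressionMatrix(m.values[cols], "log2",
                                  m.feature_annotations.copy(),
                                  m.lane_annotations.loc[cols].copy())
        labels = column_partition(sub, k=6)
        ann = sub.lane_annotations
        by_sample = {}
        for col, lab in zip(ann.index, labels):
            by_sample.setdefault(ann.loc[col, "sample_number"], []).append(lab)
        for sample, labs in by_sample.items():
            assert len(labs) == 2 and labs[0] == labs[1], sample

    def test_column_partition_invariant_to_input_order(self):
        cfg = nc.SyntheticConfig(n_features=100, seed=33)
        m, _ = nc.generate_log2(cfg)
        cols = m.lanes_where(scan_index=1)[:12]
        sub = nc.ExpressionMatrix(m.values[cols], "log2",
                                  m.feature_annotations.copy(),
                                  m.lane_annotations.loc[cols].copy())
        labels = column_partition(sub, k=3)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(cols)))
        cols_p = [cols[i] for i in perm]
        sub_p = nc.ExpressionMatrix(m.values[cols_p], "log2",
                                    m.feature_annotations.copy(),
                                    m.lane_annotations.loc[cols_p].copy())
        labels_p = column_partition(sub_p, k=3)
        # compare induced partitions as sets of column-name blocks
        def blocks(names, labs):
            out = {}
            for n, l in zip(names, labs):
                out.setdefault(l, set()).add(n)
            return {frozenset(v) for v in out.values()}
        assert blocks(cols, labels) == blocks(cols_p, labels_p)

    def test_heatmap_writes_files_and_orders(self, default_matrix, tmp_path):
        matrix, _ = default_matrix
        out = tmp_path / "heatmap.png"
        result = nc.cluster_heatmap(matrix, out)
        assert sorted(result.row_order) == list(range(matrix.n_features))
        assert sorted(result.col_order) == list(range(matrix.n_lanes))
        assert (np.diff(result.row_heights) >= -1e-12).all()
        assert out.exists() and out.with_suffix(".tsv").exists()

    def test_degenerate_identical_matrix(self):
        m = make_matrix(
            {"1_A_1": [1.0, 1.0], "1_B_1": [1.0, 1.0]},
            [("miR-0", CodeClass.ENDOGENOUS), ("miR-1", CodeClass.ENDOGENOUS)],
            [("A", 1, 1, 1), ("B", 1, 1, 1)],
            scale="log2",
        )
        result = nc.cluster_heatmap(m, out=None)
        assert np.allclose(result.row_heights, 0.0)
        assert np.allclose(result.col_heights, 0.0)
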
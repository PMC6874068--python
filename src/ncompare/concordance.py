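"""Lane-level concordance: Pearson correlations, clustering, heatmap.

Technical agreement between cartridges (and between repeated scans of the
same cartridge) is summarized as the Pearson correlation of log2 expression
across all retained features for each matched lane pair — one value per
biological sample x replicate, 12 per comparison on the full design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import NCompareError, PairingError, UndefinedStatisticError
from .io import ExpressionMatrix


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero-variance lane: Pearson correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _pcc_rows(matrix: ExpressionMatrix, pairs: list[tuple[str, str, int, int]],
              label: str, context: str) -> pd.DataFrame:
    if matrix.n_features < 3:
        raise NCompareError("need >= 3 shared features for a meaningful correlation")
    rows = []
    for col_a, col_b, sample, rep in pairs:
        pcc = _pearson(matrix.values[col_a].to_numpy(), matrix.values[col_b].to_numpy())
        rows.append((label, context, sample, rep, pcc, matrix.n_features))
    return pd.DataFrame(
        rows, columns=["pair", "context", "sample_number", "replicate", "pcc", "n_features"]
    )


def pairwise_pcc(matrix: ExpressionMatrix, pair: tuple[str, str],
                 scan_index: int) -> pd.DataFrame:
    """Per-lane PCC between two cartridges at one scan.

    Lanes are matched across cartridges by (sample_number, replicate); on the
    full design each comparison yields 12 correlations.
    """
    c1, c2 = pair
    lookup = matrix.lane_lookup()
    cells = sorted(
        {(r.sample_number, r.replicate)
         for _, r in matrix.lane_annotations.iterrows()
         if r.cartridge == c1 and r.scan_index == scan_index}
    )
    if not cells:
        raise PairingError(f"cartridge {c1} has no lanes at scan {scan_index}")
    pairs = []
    for sample, rep in cells:
        key1, key2 = (c1, scan_index, sample, rep), (c2, scan_index, sample, rep)
        for key, cart in ((key1, c1), (key2, c2)):
            if key not in lookup:
                raise PairingError(
                    f"no lane for cartridge {cart}, scan {scan_index}, "
                    f"sample {sample}, replicate {rep}"
                )
        pairs.append((lookup[key1], lookup[key2], sample, rep))
    return _pcc_rows(matrix, pairs, f"{c1}-vs-{c2}", f"scan{scan_index}")


def scanpair_pcc(matrix: ExpressionMatrix, cartridge: str) -> pd.DataFrame:
    """Per-lane PCC between the two scans of one cartridge (same physical lane)."""
    lookup = matrix.lane_lookup()
    cells = sorted(
        {(r.sample_number, r.replicate)
         for _, r in matrix.lane_annotations.iterrows() if r.cartridge == cartridge}
    )
    if not cells:
        raise PairingError(f"cartridge {cartridge} absent from matrix")
    pairs = []
    for sample, rep in cells:
        keys = [(cartridge, scan, sample, rep) for scan in (1, 2)]
        for key in keys:
            if key not in lookup:
                raise PairingError(
                    f"cartridge {cartridge} sample {sample} replicate {rep}: "
                    f"missing scan {key[1]}"
                )
        pairs.append((lookup[keys[0]], lookup[keys[1]], sample, rep))
    return _pcc_rows(matrix, pairs, f"{cartridge}-scan1-vs-scan2", "cross_scan")


def pcc_range(table: pd.DataFrame) -> tuple[float, float]:
    """(min, max) of the ``pcc`` column."""
    if len(table) == 0:
        raise NCompareError("empty PCC table has no range")
    return float(table["pcc"].min()), float(table["pcc"].max())


@dataclass
class ClusterResult:
    """Row/column orders and merge heights from two-way clustering."""

    row_order: list[int]
    col_order: list[int]
    row_heights: np.ndarray
    col_heights: np.ndarray
    linkage_method: str
    distance_metric: str


def _safe_linkage(data: np.ndarray, metric: str, method: str) -> np.ndarray:
    d = pdist(data, metric=metric)
    return hierarchy.linkage(d, method=method)


def cluster_heatmap(matrix: ExpressionMatrix, out: str | Path | None = None,
                    metric: str = "euclidean", method: str = "average") -> ClusterResult:
    """Two-way agglomerative clustering with an optional heatmap export.

    Rows (features) and columns (lanes) are clustered independently
    (default Euclidean distance, average linkage).  When ``out`` is given,
    a green-black-red heatmap (low-medium-high, symmetric about the matrix
    median) and a reordered-matrix TSV are written next to it.
    """
    if matrix.n_features < 2 or matrix.n_lanes < 2:
        raise NCompareError("clustering needs at least 2 features and 2 lanes")
    data = matrix.values.to_numpy(dtype=float)
    row_link = _safe_linkage(data, metric, method)
    col_link = _safe_linkage(data.T, metric, method)
    row_order = list(hierarchy.leaves_list(row_link))
    col_order = list(hierarchy.leaves_list(col_link))
    result = ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_heights=row_link[:, 2].copy(),
        col_heights=col_link[:, 2].copy(),
        linkage_method=method,
        distance_metric=metric,
    )
    if out is not None:
        out = Path(out)
        reordered = matrix.values.iloc[row_order, col_order]
        reordered.to_csv(out.with_suffix(".tsv"), sep="\t")
        _plot_heatmap(reordered, out)
    return result


def column_partition(matrix: ExpressionMatrix, k: int,
                     metric: str = "euclidean", method: str = "average") -> np.ndarray:
    """Flat k-cluster labels for the lanes (top-of-dendrogram cut)."""
    link = _safe_linkage(matrix.values.to_numpy(dtype=float).T, metric, method)
    return hierarchy.fcluster(link, t=k, criterion="maxclust")


def _plot_heatmap(reordered: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list("green_black_red", ["green", "black", "red"])
    center = float(np.median(reordered.to_numpy()))
    vmin, vmax = float(reordered.min().min()), float(reordered.max().max())
    span = max(vmax - center, center - vmin) or 1.0
    norm = TwoSlopeNorm(vcenter=center, vmin=center - span, vmax=center + span)
    fig, ax = plt.subplots(figsize=(10, 8))
    im = ax.imshow(reordered.to_numpy(), aspect="auto", cmap=cmap, norm=norm,
                   interpolation="nearest")
    ax.set_xticks(range(reordered.shape[1]))
    ax.set_xticklabels(reordered.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("lane")
    ax.set_ylabel("feature (clustered)")
    fig.colorbar(im, ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
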
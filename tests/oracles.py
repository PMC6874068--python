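"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's computational paths: sums of squares
come from stepwise least-squares projections on explicit design matrices,
and LOESS values from explicitly assembled weighted normal equations.
"""

import math

import numpy as np
import pandas as pd


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def sequential_ss_projection(y, annotations: pd.DataFrame, spec) -> dict:
    """Sequential (model-order) SS by stepwise residual reduction.

    Each term's dummy columns are appended to the growing design matrix and
    the SS is the drop in residual sum of squares; the final residual RSS is
    the full-model residual.  Rank deficiencies are handled by lstsq.
    """
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    prev = _rss(y, X)
    out = {}
    for term in spec.terms:
        labels = term.label_fn(annotations, spec.design)
        dummies = pd.get_dummies(labels).to_numpy(dtype=float)  # NaN rows -> all-zero
        X = np.hstack([X, dummies])
        cur = _rss(y, X)
        out[term.name] = prev - cur
        prev = cur
    out["residual"] = prev
    return out


def loess_point(x, y, span: float, degree: int, x0: float) -> float:
    """LOESS value at one point via explicit tricube-weighted normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 1, math.ceil(span * n))
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    dmax = d[idx].max()
    if dmax == 0:
        return float(y[idx].mean())
    w = (1.0 - (d[idx] / dmax) ** 3) ** 3
    X = np.vander(x[idx], N=degree + 1, increasing=True)
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx])
    return float(np.polyval(beta[::-1], x0))
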
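"""Sample distance correlation (V-statistic) for 1-D variables.

The classical biased estimator: double-center the pairwise absolute-difference
matrices of each variable, then

    dCov^2(x, y) = mean(A * B),   dCor = dCov / sqrt(dVar(x) dVar(y))

Degenerate inputs (zero distance variance, i.e. a constant vector) map to 0 by
convention. A batched variant computes one query vector against many
candidates at once; barcode vectors are short (one entry per component), so
the O(k^2) pairwise work is cheap and the batching keeps Python overhead out
of permutation loops.
"""

from __future__ import annotations

import numpy as np

__all__ = ["distance_correlation", "centered_distances", "dcor_matrix"]


def centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered pairwise |x_i - x_j| matrix of a 1-D vector."""
    x = np.asarray(x, dtype=float).ravel()
    d = np.abs(x[:, None] - x[None, :])
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def _centered_batch(M: np.ndarray) -> np.ndarray:
    """Double-centered distance matrices for each row of ``M`` (b x k -> b x k x k)."""
    d = np.abs(M[:, :, None] - M[:, None, :])
    row = d.mean(axis=2, keepdims=True)
    col = d.mean(axis=1, keepdims=True)
    grand = d.mean(axis=(1, 2))[:, None, None]
    return d - row - col + grand


def distance_correlation(x, y) -> float:
    """Distance correlation between two equal-length 1-D vectors, in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    A = centered_distances(x)
    B = centered_distances(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    dcov2 = (A * B).mean()
    # numerical noise can push dcov2 a hair negative for near-independent data
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def distance_correlation_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Distance correlation of one vector ``x`` against each row of ``Y``."""
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != x.size:
        raise ValueError("Y must be (batch, len(x))")
    A = centered_distances(x)
    dvar_x = (A * A).mean()
    B = _centered_batch(Y)
    k2 = x.size ** 2
    dvar_y = np.einsum("bij,bij->b", B, B) / k2
    if dvar_x <= 0.0:
        return np.zeros(Y.shape[0])
    dcov2 = np.einsum("ij,bij->b", A, B) / k2
    out = np.zeros(Y.shape[0])
    ok = dvar_y > 0.0
    out[ok] = np.sqrt(np.clip(dcov2[ok], 0.0, None) / np.sqrt(dvar_x * dvar_y[ok]))
    return out


def dcor_matrix(M: np.ndarray) -> np.ndarray:
    """All-pairs distance correlation between the rows of ``M`` (n x k -> n x n).

    Rows with zero distance variance (constant vectors) get 0 against
    everything and 1 on the diagonal by the same convention as the scalar
    function, except a constant row's self-dCor which is also 0 (its distance
    variance is 0).
    """
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    A = _centered_batch(M).reshape(n, k * k)
    dcov2 = (A @ A.T) / (k * k)
    dvar = np.diag(dcov2).copy()
    out = np.zeros((n, n))
    ok = dvar > 0
    denom = np.sqrt(np.sqrt(np.outer(dvar[ok], dvar[ok])))
    out[np.ix_(ok, ok)] = np.sqrt(np.clip(dcov2[np.ix_(ok, ok)], 0.0, None)) / denom
    np.fill_diagonal(out, np.where(dvar > 0, 1.0, 0.0))
    return out
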
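"""Independent brute-force oracles, deliberately written with explicit loops
and kept apart from the package implementations they check."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def dcor_bruteforce(x, y) -> float:
    """Distance correlation via literal double-centering, O(n^2) loops."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(d):
        row = [sum(d[i]) / n for i in range(n)]
        col = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[d[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A = center(a)
    B = center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvar_x = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvar_y = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvar_x * dvar_y))


def welch_t_bruteforce(members, nonmembers) -> list[float]:
    """Per-column Welch T from the textbook formula."""
    members = np.asarray(members, dtype=float)
    nonmembers = np.asarray(nonmembers, dtype=float)
    out = []
    for c in range(members.shape[1]):
        m1, m2 = members[:, c], nonmembers[:, c]
        n1, n2 = len(m1), len(m2)
        s1 = sum((v - m1.mean()) ** 2 for v in m1) / (n1 - 1)
        s2 = sum((v - m2.mean()) ** 2 for v in m2) / (n2 - 1)
        denom = math.sqrt(s1 / n1 + s2 / n2)
        out.append(0.0 if denom == 0 else (m1.mean() - m2.mean()) / denom)
    return out


def auc_pair_counting(a, b) -> float:
    """AUC by exhaustive concordant/tied pair counting."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    wins = 0.0
    for va in a:
        for vb in b:
            if va > vb:
                wins += 1.0
            elif va == vb:
                wins += 0.5
    return wins / (len(a) * len(b))


def kde_tail_bruteforce(observed: float, samples, bandwidth: float) -> float:
    """Gaussian-mixture survival probability above ``observed``: mean of the
    per-sample Gaussian survival functions."""
    total = 0.0
    for s in samples:
        total += stats.norm.sf((observed - s) / bandwidth)
    return total / len(samples)
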
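"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops straight from the defining
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def pearson(x, y) -> float:
    """Closed-form Pearson: sum((x-xbar)(y-ybar)) / sqrt(S_xx * S_yy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    num = float(((x - xbar) * (y - ybar)).sum())
    den = math.sqrt(float(((x - xbar) ** 2).sum()) * float(((y - ybar) ** 2).sum()))
    return num / den


def low_order(data: np.ndarray) -> np.ndarray:
    t, n = data.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pearson(data[:, i], data[:, j])
    return out


def corr_of_corr(lon: np.ndarray) -> np.ndarray:
    n = lon.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ci = [lon[i, k] for k in range(n) if k not in (i, j)]
            cj = [lon[j, k] for k in range(n) if k not in (i, j)]
            out[i, j] = out[j, i] = pearson(ci, cj)
    return out


def incidence(lon: np.ndarray, t: float) -> np.ndarray:
    n = lon.shape[0]
    H = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j or lon[i, j] >= t:
                H[i, j] = 1
    return H


def hyperedge_series(data: np.ndarray, H: np.ndarray) -> np.ndarray:
    t, n = data.shape
    out = np.zeros((t, n))
    for j in range(n):
        members = [i for i in range(n) if H[i, j] == 1]
        for tp in range(t):
            out[tp, j] = sum(data[tp, i] for i in members) / len(members)
    return out


def hypergraph_hon(data: np.ndarray, threshold: float) -> np.ndarray:
    """End-to-end composition: Pearson FCN -> threshold -> average -> Pearson."""
    lon = low_order(data)
    H = incidence(lon, threshold)
    hs = hyperedge_series(data, H)
    return low_order(hs)


def welch_t_pvalue(a, b) -> float:
    """Two-sided Welch two-sample t-test from the closed-form statistic."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t_stat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * t_dist.sf(abs(t_stat), df)


def lasso_kkt_violation(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Max violation of the subgradient optimality conditions of
    (1/2)||y - Xw||^2 + lam*||w||_1  (0 at an exact minimiser)."""
    g = X.T @ (y - X @ w)  # negative gradient of the smooth part
    viol = 0.0
    for j in range(len(w)):
        if w[j] > 0:
            viol = max(viol, abs(g[j] - lam))
        elif w[j] < 0:
            viol = max(viol, abs(g[j] + lam))
        else:
            viol = max(viol, max(0.0, abs(g[j]) - lam))
    return viol
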
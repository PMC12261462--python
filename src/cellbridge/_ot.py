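"""2-Wasserstein distance between empirical point clouds (uniform weights).

Exact for small problems (Hungarian assignment when sizes match, transport LP
otherwise), log-domain Sinkhorn with a small entropic regularizer for large
ones.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist

__all__ = ["w2_distance", "ot_matching"]

_EXACT_MAX = 512          # exact assignment limit when |A| == |B|
_LP_MAX_VARS = 60_000     # transport-LP limit for unequal sizes


def _sqcost(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return cdist(A, B, metric="sqeuclidean")


def _sinkhorn_cost(M: np.ndarray, reg: float, n_iter: int = 2000) -> float:
    n, m = M.shape
    loga = -np.log(n) * np.ones(n)
    logb = -np.log(m) * np.ones(m)
    f = np.zeros(n)
    g = np.zeros(m)
    for _ in range(n_iter):
        f = reg * loga - reg * _lse((-M + g[None, :]) / reg, axis=1)
        g = reg * logb - reg * _lse((-M + f[:, None]) / reg, axis=0)
    logP = (-M + f[:, None] + g[None, :]) / reg
    P = np.exp(logP)
    P /= P.sum()
    return float((P * M).sum())


def _lse(X: np.ndarray, axis: int) -> np.ndarray:
    mx = X.max(axis=axis, keepdims=True)
    out = mx.squeeze(axis) + np.log(np.exp(X - mx).sum(axis=axis))
    return out


def _lp_cost(M: np.ndarray) -> float:
    n, m = M.shape
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    rows, cols, vals = [], [], []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
        vals.extend([1.0] * m)
    for j in range(m - 1):  # last column constraint is redundant
        rows.extend([n + j] * n)
        cols.extend([i * m + j for i in range(n)])
        vals.extend([1.0] * n)
    A_eq = coo_matrix((vals, (rows, cols)), shape=(n + m - 1, n * m))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(M.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def w2_distance(A: np.ndarray, B: np.ndarray, method: str = "auto",
                reg: float | None = None, return_info: bool = False):
    """2-Wasserstein distance between point sets with uniform weights.

    Exact (assignment or transport LP) up to moderate sizes, entropic
    Sinkhorn above. Returns sqrt of the optimal squared-Euclidean cost.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty point set")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    M = _sqcost(A, B)
    n, m = M.shape
    if method == "auto":
        if n == m and n <= _EXACT_MAX:
            method = "assignment"
        elif n * m <= _LP_MAX_VARS:
            method = "lp"
        else:
            method = "sinkhorn"
    if method == "assignment":
        if n != m:
            raise ValueError("assignment method requires equal sizes")
        r, c = linear_sum_assignment(M)
        cost = float(M[r, c].mean())
    elif method == "lp":
        cost = _lp_cost(M)
    elif method == "sinkhorn":
        if reg is None:
            med = float(np.median(M))
            reg = max(1e-6, 0.005 * med)
        cost = _sinkhorn_cost(M, reg)
    else:
        raise ValueError(f"unknown method {method!r}")
    w2 = float(np.sqrt(max(cost, 0.0)))
    if return_info:
        return w2, {"method": method, "cost": cost}
    return w2


def ot_matching(A: np.ndarray, B: np.ndarray,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of an (approximately) optimal coupling between A and B.

    With equal sizes this is the exact assignment; otherwise the smaller set
    is matched against a uniform subsample of the larger one.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    rng = rng or np.random.default_rng()
    ia = np.arange(A.shape[0])
    ib = np.arange(B.shape[0])
    k = min(A.shape[0], B.shape[0])
    if A.shape[0] > k:
        ia = rng.choice(A.shape[0], size=k, replace=False)
    if B.shape[0] > k:
        ib = rng.choice(B.shape[0], size=k, replace=False)
    M = _sqcost(A[ia], B[ib])
    r, c = linear_sum_assignment(M)
    return ia[r], ib[c]
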
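"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the implementation under test.
"""

import itertools

import numpy as np
from scipy.stats import pearsonr

from ncfger import ResponseMatrix, WeightSystem


def brute_force_response_pcc(R: ResponseMatrix, axis: str, min_overlap: int):
    """Per-pair response correlation over explicit overlap index sets."""
    V = R.values if axis == "drugs" else R.values.T
    M = R.observed if axis == "drugs" else R.observed.T
    k = V.shape[1]
    S = np.zeros((k, k))
    support = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            overlap = np.flatnonzero(M[:, i] & M[:, j])
            support[i, j] = overlap.size
            if overlap.size < max(min_overlap, 2):
                continue
            x, y = V[overlap, i], V[overlap, j]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            S[i, j] = pearsonr(x, y).statistic
    return S, support


def brute_force_weight_system(R: ResponseMatrix, u: int, i: int, neighbors, beta: float):
    """Double-loop shrunk normal equations (drug orientation)."""
    V, M = R.values, R.observed
    K = len(neighbors)
    A_bar = np.zeros((K, K))
    N = np.zeros((K, K))
    for a, j in enumerate(neighbors):
        for c, k in enumerate(neighbors):
            rows = [v for v in range(R.m) if v != u and M[v, j] and M[v, k]]
            N[a, c] = len(rows)
            if rows:
                A_bar[a, c] = sum(V[v, j] * V[v, k] for v in rows) / len(rows)
    b_bar = np.zeros(K)
    Nb = np.zeros(K)
    for a, j in enumerate(neighbors):
        rows = [v for v in range(R.m) if v != u and M[v, j] and M[v, i]]
        Nb[a] = len(rows)
        if rows:
            b_bar[a] = sum(V[v, j] * V[v, i] for v in rows) / len(rows)
    avg = A_bar[N > 0].mean() if (N > 0).any() else 0.0
    with np.errstate(invalid="ignore"):
        A_hat = np.where(N + beta > 0, (N * A_bar + beta * avg) / np.maximum(N + beta, 1e-300), 0.0)
        b_hat = np.where(Nb + beta > 0, (Nb * b_bar + beta * avg) / np.maximum(Nb + beta, 1e-300), 0.0)
    return A_bar, b_bar, A_hat, b_hat, avg


def enumerate_active_sets(A, b):
    """Exhaustive oracle for min_{w>=0} w'Aw - 2b'w: try every pattern of
    zero/free coordinates and keep the feasible candidate with the lowest
    objective."""
    K = len(b)
    best_obj, best_w = np.inf, None
    for pattern in itertools.product([0, 1], repeat=K):
        free = [idx for idx in range(K) if pattern[idx]]
        w = np.zeros(K)
        if free:
            try:
                w[free] = np.linalg.solve(A[np.ix_(free, free)], b[free])
            except np.linalg.LinAlgError:
                continue
        if (w < -1e-12).any():
            continue
        obj = w @ A @ w - 2 * b @ w
        if obj < best_obj:
            best_obj, best_w = obj, w
    return best_w, best_obj


def qp_objective(w, system: WeightSystem):
    A = 0.5 * (system.A_hat + system.A_hat.T)
    return float(w @ A @ w - 2 * system.b_hat @ w)
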
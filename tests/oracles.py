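"""Independent oracles used by the test suite.

Everything here evaluates the quantities of interest by direct, dense or
exhaustive computation — densified probability vectors, brute-force pair
counting, enumeration of sequential weighted draws — never through the
package's lazy / heap / incremental code paths.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.special import rel_entr


# --------------------------------------------------------------------------
# dense divergence formulas on raw count vectors


def dense_prob(x: np.ndarray, beta: float) -> np.ndarray:
    """Densified prior-adjusted probability vector (beta=0: plain normalize)."""
    x = np.asarray(x, dtype=np.float64)
    return (x + beta) / (x.sum() + x.size * beta)


def dense_distance(x: np.ndarray, y: np.ndarray, measure: str, beta: float = 0.0) -> float:
    """Distance between raw vectors by full dense instantiation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    measure = measure.upper()
    if measure == "SQE":
        return float(((x - y) ** 2).sum())
    if measure == "COS":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return 1.0
        return float(1.0 - x @ y / (nx * ny))
    p, q = dense_prob(x, beta), dense_prob(y, beta)
    return dense_prob_distance(p, q, measure)


def dense_prob_distance(p: np.ndarray, q: np.ndarray, measure: str) -> float:
    """Distance between ready-made probability vectors."""
    measure = measure.upper()
    if measure == "KLD":
        return float(rel_entr(p, q).sum())
    if measure == "JSD":
        m = 0.5 * (p + q)
        return float(0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()))
    if measure == "BATMET":
        return float(math.sqrt(max(0.0, 1.0 - np.sqrt(p * q).sum())))
    raise ValueError(measure)


def dense_row_to_center(x_raw: np.ndarray, center: np.ndarray,
                        measure: str, beta: float = 0.0) -> float:
    """Row (raw counts) to a center already in the working representation."""
    measure = measure.upper()
    x_raw = np.asarray(x_raw, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    if measure == "SQE":
        return float(((x_raw - center) ** 2).sum())
    if measure == "COS":
        nx, nc = np.linalg.norm(x_raw), np.linalg.norm(center)
        if nx == 0 or nc == 0:
            return 1.0
        return float(max(0.0, 1.0 - x_raw @ center / (nx * nc)))
    return dense_prob_distance(dense_prob(x_raw, beta), center, measure)


# --------------------------------------------------------------------------
# weighted sampling without replacement: exact set probabilities


def subset_probabilities(weights: Sequence[float], m: int) -> Dict[Tuple[int, ...], float]:
    """P[drawn set] for m sequential weighted draws without replacement,
    by exhaustive enumeration over ordered draw sequences."""
    w = np.asarray(weights, dtype=np.float64)
    pos = [i for i in range(w.size) if w[i] > 0]
    m_eff = min(m, len(pos))
    probs: Dict[Tuple[int, ...], float] = {}
    for perm in itertools.permutations(pos, m_eff):
        p = 1.0
        remaining = w[pos].sum()
        for i in perm:
            p *= w[i] / remaining
            remaining -= w[i]
        key = tuple(sorted(perm))
        probs[key] = probs.get(key, 0.0) + p
    return probs


# --------------------------------------------------------------------------
# adjusted Rand index by direct pair counting


def ari_pair_counting(pred: Sequence, truth: Sequence) -> float:
    """ARI from agreements/disagreements over all unordered row pairs."""
    pred = list(pred)
    truth = list(truth)
    n = len(pred)
    a = b = c = d = 0  # together/together, t/s, s/t, separate/separate
    for i in range(n):
        for j in range(i + 1, n):
            same_p = pred[i] == pred[j]
            same_t = truth[i] == truth[j]
            if same_p and same_t:
                a += 1
            elif same_p:
                b += 1
            elif same_t:
                c += 1
            else:
                d += 1
    num = 2.0 * (a * d - b * c)
    den = (a + b) * (b + d) + (a + c) * (c + d)
    if den == 0:
        return 0.0
    return num / den


# --------------------------------------------------------------------------
# exact 1-D k-means optimum (optimal SQE clusters of sorted 1-D data are
# contiguous, so enumerating contiguous partitions is exhaustive)


def optimal_1d_kmeans_cost(values: Sequence[float], k: int) -> float:
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size

    def sse(lo: int, hi: int) -> float:  # [lo, hi)
        seg = v[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        cost = sum(sse(lo, hi) for lo, hi in zip(edges, edges[1:]))
        best = min(best, cost)
    return best


# --------------------------------------------------------------------------
# dense Lloyd reference (densified probability vectors, same update rules)


def dense_lloyd_trace(raw: np.ndarray, init_centers: np.ndarray, measure: str,
                      beta: float, n_iter: int) -> list:
    """Cost trace of Lloyd's algorithm on the densified representation."""
    probs = np.stack([dense_prob(r, beta) for r in raw])
    centers = np.asarray(init_centers, dtype=np.float64).copy()
    k = centers.shape[0]
    trace = []

    def assign_cost():
        dists = np.stack(
            [[dense_prob_distance(p, c, measure) for c in centers] for p in probs]
        )
        a = dists.argmin(axis=1)
        return a, float(dists.min(axis=1).sum()), dists.min(axis=1)

    a, cost, costs = assign_cost()
    trace.append(cost)
    for _ in range(n_iter):
        for j in range(k):
            members = probs[a == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                centers[j] = probs[int(np.argmax(costs))]
        a, cost, costs = assign_cost()
        trace.append(cost)
    return trace
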
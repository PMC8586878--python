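"""Clustering quality: objective cost reporting and the Adjusted Rand Index.

The ARI is the Hubert–Arabie chance-corrected pairwise agreement between
two partitions of the same rows: 1 for identical partitions (up to label
renaming), approximately 0 for independent labelings, negative for
worse-than-chance agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .clustering import ClusterResult

__all__ = ["ContingencyTable", "contingency_table", "adjusted_rand_index", "report"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two labelings: counts[i, j] = |pred i & truth j|."""

    counts: np.ndarray
    pred_labels: np.ndarray
    truth_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def pred_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def truth_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency_table(pred: Sequence, truth: Sequence) -> ContingencyTable:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    counts = sp.coo_matrix(
        (np.ones(pred.size, dtype=np.int64), (pi, ti)),
        shape=(pu.size, tu.size),
    ).toarray()
    return ContingencyTable(counts=counts, pred_labels=pu, truth_labels=tu)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(pred: Sequence, truth: Sequence) -> float:
    """Hubert–Arabie ARI: (Index - Expected) / (Max - Expected).

    Invariant to label names and symmetric in its arguments. The
    degenerate case Max == Expected (e.g. both labelings a single
    cluster, or all singletons) returns 0 by convention, so trivial
    clusterings are not rewarded.
    """
    t = contingency_table(pred, truth)
    if t.n < 2:
        raise ValueError("ARI needs at least 2 rows")
    sum_ij = _comb2(t.counts.astype(np.float64)).sum()
    sum_a = _comb2(t.pred_marginals.astype(np.float64)).sum()
    sum_b = _comb2(t.truth_marginals.astype(np.float64)).sum()
    n_pairs = _comb2(np.float64(t.n))
    expected = sum_a * sum_b / n_pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


def report(
    result: ClusterResult,
    labels: Optional[Sequence] = None,
    seed: Optional[int] = None,
) -> Dict:
    """Machine-readable summary of a clustering run (stable key order).

    Keys: k, measure, prior_beta, algorithm, final_cost, iterations,
    converged, n_rows, [ari,] seed. The ARI key is present only when
    reference labels are given.
    """
    out: Dict = {
        "k": int(result.center_set.k),
        "measure": result.measure.value,
        "prior_beta": result.prior.beta if result.prior is not None else None,
        "algorithm": result.algorithm,
        "final_cost": float(result.final_cost),
        "iterations": int(result.n_iter),
        "converged": bool(result.converged),
        "n_rows": int(len(result.center_set.assignments)),
    }
    if labels is not None:
        out["ari"] = adjusted_rand_index(result.center_set.assignments, labels)
    out["seed"] = seed
    return out
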
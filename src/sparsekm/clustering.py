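"""Lloyd's k-means and mini-batch k-means over a seeded center set.

Both algorithms are generic over the divergence: assignment always uses
the active measure, and centers are updated as arithmetic means in the
measure's working representation — raw counts for SQE, prior-adjusted
probability vectors for KLD/JSD/BATMET (for Bregman divergences the mean
is the exact right-centroid minimizer; for JSD/BATMET it is the standard
practical surrogate), and L2-normalized vectors re-normalized after
averaging for COS.

Mini-batch k-means updates only the centers touched by each uniformly
drawn batch, with the per-center streaming learning rate 1/N_c where N_c
counts every batch point ever assigned to c; a full pass in a single batch
therefore reproduces one Lloyd update exactly. The full-data objective is
recorded at each epoch end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .divergences import MatrixContext, Measure, point_to_centers_costs
from .priors import Prior
from .sampling import RngLike, as_generator
from .seeding import CenterSet
from .sparse import CSRMatrix

__all__ = ["ClusterResult", "lloyd", "minibatch"]


@dataclass
class ClusterResult:
    """Outcome of a k-means optimization.

    ``trace[0]`` is the objective of the seed centers; subsequent entries
    are per-iteration (Lloyd) or per-epoch (mini-batch) full-data costs.
    """

    center_set: CenterSet
    trace: List[float]
    n_iter: int
    converged: bool
    algorithm: str
    measure: Measure
    prior: Prior
    rng_provenance: str = ""

    @property
    def final_cost(self) -> float:
        return self.center_set.total_cost()


def _reseed_empty(ctx: MatrixContext, centers: np.ndarray, counts: np.ndarray,
                  costs: np.ndarray) -> np.ndarray:
    """Reseed empty clusters to the currently worst-served rows (deterministic)."""
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        worst = np.argsort(-costs, kind="stable")[: empty.size]
        for c, r in zip(empty, worst):
            centers[c] = ctx.row_vector(int(r))
    return empty


def lloyd(
    m: CSRMatrix,
    centers: CenterSet,
    measure,
    prior: Prior = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    ctx: Optional[MatrixContext] = None,
) -> ClusterResult:
    """Full (batch) k-means: alternate assignment and mean update.

    Stops when the relative cost change drops below ``tol`` or after
    ``max_iter`` iterations. Assignments always correspond to the final
    centers (the last step is an assignment). ``max_iter = 0`` returns the
    seeds untouched.
    """
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    measure = Measure.parse(measure)
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    cs = centers.copy()
    k = cs.k

    costs, assign = point_to_centers_costs(m, cs.centers, measure, prior, ctx=ctx)
    cs.costs, cs.assignments = costs, assign
    trace = [float(costs.sum())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sums, counts = ctx.group_stats(cs.assignments, k)
        nonempty = counts > 0
        new_centers = cs.centers.copy()
        new_centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        for j in np.flatnonzero(nonempty):
            new_centers[j] = ctx.finalize_center(new_centers[j])
        _reseed_empty(ctx, new_centers, counts, cs.costs)
        cs.centers = new_centers
        cs.source_rows = np.full(k, -1, dtype=np.int64)

        costs, assign = point_to_centers_costs(m, cs.centers, measure, prior, ctx=ctx)
        cs.costs, cs.assignments = costs, assign
        cost = float(costs.sum())
        trace.append(cost)
        prev = trace[-2]
        if abs(prev - cost) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break

    return ClusterResult(center_set=cs, trace=trace, n_iter=it,
                         converged=converged, algorithm="lloyd",
                         measure=measure, prior=prior)


def minibatch(
    m: CSRMatrix,
    centers: CenterSet,
    measure,
    prior: Prior = None,
    batch_size: int = 10_000,
    max_epochs: int = 10,
    rng: RngLike = None,
    tol: float = 1e-4,
    ctx: Optional[MatrixContext] = None,
) -> ClusterResult:
    """Mini-batch k-means with per-center streaming-mean learning rates.

    Each step draws a uniform batch without replacement (within the batch),
    assigns it, and folds the batch members into their centers with rate
    1/N_c. An epoch is ceil(n / batch_size) steps; the full-data objective
    and empty-cluster reseeding happen at epoch ends.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if max_epochs < 0:
        raise ValueError("max_epochs must be >= 0")
    measure = Measure.parse(measure)
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    gen = as_generator(rng)
    cs = centers.copy()
    k, n = cs.k, m.n_rows
    if batch_size > n:
        warnings.warn(f"batch_size {batch_size} > n_rows {n}; clamping",
                      stacklevel=2)
        batch_size = n

    costs, assign = point_to_centers_costs(m, cs.centers, measure, prior, ctx=ctx)
    cs.costs, cs.assignments = costs, assign
    trace = [float(costs.sum())]
    n_seen = np.zeros(k)  # N_c: cumulative batch points ever assigned to c
    steps_per_epoch = math.ceil(n / batch_size)
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        for _ in range(steps_per_epoch):
            idx = gen.choice(n, size=batch_size, replace=False)
            _, b_assign = point_to_centers_costs(
                m, cs.centers, measure, prior, ctx=ctx, rows=idx
            )
            sums, counts = ctx.group_stats(b_assign, k, rows=idx)
            touched = counts > 0
            n_new = n_seen + counts
            cs.centers[touched] = (
                n_seen[touched, None] * cs.centers[touched] + sums[touched]
            ) / n_new[touched, None]
            n_seen = n_new

        costs, assign = point_to_centers_costs(m, cs.centers, measure, prior, ctx=ctx)
        cs.costs, cs.assignments = costs, assign
        cost = float(costs.sum())
        trace.append(cost)
        member_counts = np.bincount(assign, minlength=k).astype(float)
        empty = _reseed_empty(ctx, cs.centers, member_counts, costs)
        if empty.size:
            n_seen[empty] = 0.0
            costs, assign = point_to_centers_costs(
                m, cs.centers, measure, prior, ctx=ctx
            )
            cs.costs, cs.assignments = costs, assign
        prev = trace[-2]
        if abs(prev - cost) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break

    # COS centers are kept un-normalized during streaming (assignment is
    # scale-invariant); normalize for output.
    if measure is Measure.COS:
        for j in range(k):
            cs.centers[j] = ctx.finalize_center(cs.centers[j])
    cs.source_rows = np.full(k, -1, dtype=np.int64)
    return ClusterResult(center_set=cs, trace=trace, n_iter=epoch,
                         converged=converged, algorithm="minibatch",
                         measure=measure, prior=prior)
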
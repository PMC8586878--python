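"""k-means++ seeding and localsearch++ refinement, generic over measure.

k-means++ picks the first center uniformly at random among the rows, then
each subsequent center with probability proportional to a row's current
cost (its distance to the nearest already-chosen center). This yields an
expected O(log k) approximation of the optimal objective, a guarantee that
extends to Bregman divergences. A greedy multi-candidate variant draws
several candidates per step and keeps the one minimizing the resulting
total cost.

localsearch++ then refines the seed set: each round samples one candidate
row with probability proportional to cost and swaps it with the center
whose removal hurts the objective least, keeping the swap only when it
strictly lowers the total cost (so the objective is nonincreasing and the
procedure terminates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .divergences import MatrixContext, point_to_centers_costs
from .errors import NoMassError
from .priors import Prior
from .sampling import RngLike, as_generator, sample_without_replacement
from .sparse import CSRMatrix

__all__ = [
    "CenterSet",
    "kmeanspp",
    "localsearchpp",
    "uniform_seeding",
    "center_set_from_centers",
    "center_set_from_rows",
    "SwapRecord",
]


@dataclass
class CenterSet:
    """k centers with the per-row cost and assignment arrays they induce.

    ``centers`` is (k, d) in the measure's working representation;
    ``source_rows[j]`` is the data row a center was copied from (-1 once a
    center is a computed mean). Invariant: ``costs[i]`` is the distance of
    row i to ``centers[assignments[i]]`` and is the minimum over centers.
    """

    centers: np.ndarray
    costs: np.ndarray
    assignments: np.ndarray
    source_rows: np.ndarray

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def total_cost(self) -> float:
        return float(self.costs.sum())

    def copy(self) -> "CenterSet":
        return CenterSet(
            centers=self.centers.copy(),
            costs=self.costs.copy(),
            assignments=self.assignments.copy(),
            source_rows=self.source_rows.copy(),
        )


def center_set_from_centers(
    m: CSRMatrix,
    centers: np.ndarray,
    measure,
    prior: Prior = None,
    ctx: Optional[MatrixContext] = None,
    source_rows: Optional[np.ndarray] = None,
) -> CenterSet:
    """Wrap explicit working-representation centers into a consistent CenterSet."""
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    costs, assign = point_to_centers_costs(m, centers, measure, prior, ctx=ctx)
    if source_rows is None:
        source_rows = np.full(centers.shape[0], -1, dtype=np.int64)
    return CenterSet(centers=centers.copy(), costs=costs, assignments=assign,
                     source_rows=np.asarray(source_rows, dtype=np.int64))


def center_set_from_rows(
    m: CSRMatrix,
    rows,
    measure,
    prior: Prior = None,
    ctx: Optional[MatrixContext] = None,
) -> CenterSet:
    """Centers copied from the given data rows (working representation)."""
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    rows = np.asarray(rows, dtype=np.int64)
    centers = np.stack([ctx.row_vector(int(r)) for r in rows])
    return center_set_from_centers(m, centers, measure, prior, ctx=ctx,
                                   source_rows=rows)


def _default_candidates(k: int) -> int:
    return 1 + int(math.floor(math.log2(k))) if k > 1 else 1


def kmeanspp(
    m: CSRMatrix,
    k: int,
    measure,
    prior: Prior = None,
    n_candidates: Optional[int] = None,
    rng: RngLike = None,
    ctx: Optional[MatrixContext] = None,
) -> CenterSet:
    """k-means++ seeding: k data rows chosen by cost-proportional sampling.

    ``n_candidates`` > 1 enables the greedy variant (default
    1 + floor(log2 k)); each step evaluates every candidate's would-be
    total cost and keeps the argmin. Per-row costs are elementwise minima
    across steps, hence monotone nonincreasing.
    """
    n = m.n_rows
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n_candidates is None:
        n_candidates = _default_candidates(k)
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    gen = as_generator(rng)

    d = m.n_cols
    centers = np.empty((k, d))
    source = np.full(k, -1, dtype=np.int64)

    first = int(gen.integers(n))
    centers[0] = ctx.row_vector(first)
    source[0] = first
    costs = ctx.distances_to_center(centers[0])
    costs = np.maximum(costs, 0.0)
    assign = np.zeros(n, dtype=np.int64)

    for step in range(1, k):
        total = costs.sum()
        if total <= 0:
            # every row coincides with a chosen center: duplicate-tolerant fill
            warnings.warn(
                "fewer distinct rows than k; duplicating centers", stacklevel=2
            )
            remaining = np.setdiff1d(np.arange(n), source[:step])
            fill = remaining[0] if remaining.size else first
            for j in range(step, k):
                centers[j] = ctx.row_vector(int(fill))
                source[j] = int(fill)
            break
        try:
            cand = sample_without_replacement(costs, n_candidates, gen).indices
        except NoMassError:  # pragma: no cover - guarded by total above
            break
        best_row, best_cost_vec, best_total = -1, None, np.inf
        for z in cand:
            cz = ctx.row_vector(int(z))
            dz = ctx.distances_to_center(cz)
            newc = np.minimum(costs, dz)
            t = newc.sum()
            if t < best_total:
                best_row, best_total = int(z), t
                best_cost_vec, best_dz = newc, dz
        centers[step] = ctx.row_vector(best_row)
        source[step] = best_row
        assign = np.where(best_dz < costs, step, assign)
        costs = best_cost_vec

    return CenterSet(centers=centers, costs=costs, assignments=assign,
                     source_rows=source)


def uniform_seeding(
    m: CSRMatrix,
    k: int,
    measure,
    prior: Prior = None,
    rng: RngLike = None,
    ctx: Optional[MatrixContext] = None,
) -> CenterSet:
    """Baseline seeding: k distinct rows chosen uniformly at random."""
    n = m.n_rows
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    gen = as_generator(rng)
    rows = gen.choice(n, size=k, replace=False)
    centers = np.stack([ctx.row_vector(int(r)) for r in rows])
    costs, assign = point_to_centers_costs(m, centers, measure, prior, ctx=ctx)
    return CenterSet(centers=centers, costs=costs, assignments=assign,
                     source_rows=np.asarray(rows, dtype=np.int64))


@dataclass
class SwapRecord:
    """One localsearch++ round, for auditing against an exhaustive oracle."""

    candidate_row: int
    swap_objectives: np.ndarray  # objective of replacing each center with z
    removed_center: Optional[int]  # None when no swap improved the cost
    total_cost_after: float


def localsearchpp(
    m: CSRMatrix,
    centers: CenterSet,
    rounds: int,
    measure,
    prior: Prior = None,
    rng: RngLike = None,
    ctx: Optional[MatrixContext] = None,
    return_trace: bool = False,
):
    """Cost-sampled single-swap refinement of a seeded center set.

    Each round: (1) sample a candidate row z with probability proportional
    to the current per-row cost; (2) for every center c, evaluate the
    objective of (centers - {c}) u {z}; (3) apply the best swap iff it
    strictly lowers the total cost. The total cost is nonincreasing across
    rounds. Returns a new CenterSet (and the per-round trace when
    ``return_trace``).
    """
    if rounds < 0:
        raise ValueError(f"rounds must be >= 0, got {rounds}")
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    gen = as_generator(rng)
    cs = centers.copy()
    trace: List[SwapRecord] = []
    if rounds == 0:
        return (cs, trace) if return_trace else cs

    k, n = cs.k, m.n_rows
    # full row-by-center distance matrix; O(nk) memory, exact swap evaluation
    D = np.empty((n, k))
    for j in range(k):
        D[:, j] = ctx.distances_to_center(cs.centers[j])
    assign = np.argmin(D, axis=1)
    best = D[np.arange(n), assign]
    total = best.sum()

    for _ in range(rounds):
        if total <= 0:
            break
        z = int(sample_without_replacement(best, 1, gen).indices[0])
        cz = ctx.row_vector(z)
        dz = ctx.distances_to_center(cz)
        if k > 1:
            second = np.partition(D, 1, axis=1)[:, 1]
        else:
            second = np.full(n, np.inf)
        objs = np.empty(k)
        for c in range(k):
            base = np.where(assign == c, second, best)
            objs[c] = np.minimum(base, dz).sum()
        c_star = int(np.argmin(objs))
        if objs[c_star] < total:
            D[:, c_star] = dz
            cs.centers[c_star] = cz
            cs.source_rows[c_star] = z
            assign = np.argmin(D, axis=1)
            best = D[np.arange(n), assign]
            total = best.sum()
            removed = c_star
        else:
            removed = None
        trace.append(SwapRecord(candidate_row=z, swap_objectives=objs,
                                removed_center=removed, total_cost_after=total))

    cs.costs = best
    cs.assignments = assign
    return (cs, trace) if return_trace else cs
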
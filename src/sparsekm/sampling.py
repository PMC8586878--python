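"""Weighted sampling without replacement via exponential random keys.

Drawing m items without replacement from weights (w_1, ..., w_n) — where
each successive item is drawn from the remaining items with probability
proportional to its weight — is equivalent to assigning every item an
independent key E_i = -ln(u_i) / w_i with u_i ~ U(0, 1) (an Exp(w_i)
variate) and keeping the m items with the *smallest* keys. The -ln(u)/w
form is used rather than the equivalent u^(1/w) because it is numerically
stable for small weights.

Because keys are independent per item, partial samples built over disjoint
index ranges (each with its own named random stream) can be merged by
taking the global top-m smallest keys; the result is identical no matter
how the ranges are grouped across workers. This kernel drives both
k-means++ seeding and localsearch++ candidate selection.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

import numpy as np

from .errors import NoMassError

__all__ = [
    "WeightedSample",
    "exp_keys",
    "sample_without_replacement",
    "merge_partial_samples",
    "sample_partitioned",
    "stream_rng",
    "as_generator",
]

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_generator(rng: RngLike) -> np.random.Generator:
    """Coerce to a Generator; integer seeds get a counter-based Philox stream."""
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, np.random.SeedSequence):
        return np.random.Generator(np.random.Philox(rng))
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(rng)))


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """A named, reproducible stream: the same (seed, stream) pair always
    yields the same generator, independent of any other stream."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence((int(seed), int(stream))))
    )


@dataclass(frozen=True)
class WeightedSample:
    """Result of one weighted draw of up to m items.

    ``indices`` are global item indices, ``keys`` the exponential variates
    that selected them (ascending). ``index_range`` is the half-open global
    range the sample covers, used to verify disjointness when merging.
    ``provenance`` records how the randomness was seeded.
    """

    indices: np.ndarray
    keys: np.ndarray
    index_range: Tuple[int, int]
    provenance: str = ""

    def __post_init__(self):
        if len(self.indices) != len(self.keys):
            raise ValueError("indices and keys must align")


def exp_keys(weights: Sequence[float], rng: RngLike) -> np.ndarray:
    """Exponential random keys: key_i = -ln(u_i) / w_i, u_i ~ U(0, 1).

    Zero-weight items receive key = +inf and are therefore never selected;
    index alignment with the weight array is preserved. Raises
    :class:`NoMassError` when no weight is positive.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1:
        raise ValueError("weights must be 1-D")
    if np.any(w < 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    if not np.any(w > 0):
        raise NoMassError("all weights are zero")
    gen = as_generator(rng)
    u = gen.random(w.size)
    keys = np.full(w.size, np.inf)
    pos = w > 0
    # -log1p(-u) is an Exp(1) variate from u in [0,1), never -ln(0)
    keys[pos] = -np.log1p(-u[pos]) / w[pos]
    return keys


def _top_m_heap(keys: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m smallest keys via a bounded max-heap.

    A candidate enters only if its key beats the current heap ceiling, so
    heap updates become rare as the scan proceeds.
    """
    heap: list = []  # (-key, -index): max-heap on key, ties evict higher index
    for i, k in enumerate(keys):
        if k == np.inf:
            continue
        if len(heap) < m:
            heapq.heappush(heap, (-k, -i))
        elif -heap[0][0] > k:
            heapq.heapreplace(heap, (-k, -i))
    order = sorted((-nk, -ni) for nk, ni in heap)
    return np.array([i for _, i in order], dtype=np.int64)


def sample_without_replacement(
    weights: Sequence[float],
    m: int,
    rng: RngLike,
    offset: int = 0,
) -> WeightedSample:
    """Draw up to m distinct items with probability proportional to weight.

    Distributionally identical to m sequential draws from the successively
    renormalized multinomial. When fewer than m weights are positive, all
    positive-weight items are returned. ``offset`` shifts the reported
    indices into a global index space (for partitioned sampling).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    keys = exp_keys(weights, rng)
    chosen = _top_m_heap(keys, m)
    return WeightedSample(
        indices=chosen + offset,
        keys=keys[chosen],
        index_range=(offset, offset + len(keys)),
        provenance=f"single-range offset={offset}",
    )


def merge_partial_samples(
    samples: Iterable[WeightedSample], m: int
) -> WeightedSample:
    """Combine partial samples over disjoint index ranges: global top-m keys."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to merge")
    ranges = sorted(s.index_range for s in samples)
    for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
        if lo2 < hi1:
            raise ValueError(
                f"overlapping index ranges: [{lo1},{hi1}) and [{lo2},{hi2})"
            )
    idx = np.concatenate([s.indices for s in samples])
    keys = np.concatenate([s.keys for s in samples])
    if len(idx) > m:
        part = np.argsort(keys, kind="stable")[:m]
    else:
        part = np.argsort(keys, kind="stable")
    return WeightedSample(
        indices=idx[part],
        keys=keys[part],
        index_range=(min(r[0] for r in ranges), max(r[1] for r in ranges)),
        provenance="merged",
    )


def sample_partitioned(
    weights: Sequence[float],
    m: int,
    seed: int,
    boundaries: Sequence[int],
) -> WeightedSample:
    """Partitioned draw: one named stream per index range, then a merge.

    ``boundaries`` are the interior split points of [0, n). For a fixed
    partition the result is byte-identical however the ranges are scheduled
    across workers, because each range's stream is keyed by (seed, lo).
    """
    w = np.asarray(weights, dtype=np.float64)
    if not np.any(w > 0):
        raise NoMassError("all weights are zero")
    edges = [0, *sorted(int(b) for b in boundaries), w.size]
    partials = []
    for lo, hi in zip(edges, edges[1:]):
        if hi <= lo:
            continue
        chunk = w[lo:hi]
        if not np.any(chunk > 0):
            continue
        partials.append(
            sample_without_replacement(chunk, m, stream_rng(seed, lo), offset=lo)
        )
    return merge_partial_samples(partials, m)
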
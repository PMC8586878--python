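"""Dissimilarity measures on sparse count vectors, evaluated in O(nnz).

Five measures are supported, named by their conventional abbreviations:

==========  ====================================================================
SQE         squared Euclidean distance, sum_i (X_i - Y_i)^2, on raw counts
KLD         Kullback-Leibler divergence sum_i X^_i ln(X^_i / Y^_i)
JSD         Jensen-Shannon divergence, 0.5*(KLD(X, M) + KLD(Y, M)), M = (X^+Y^)/2
BATMET      Bhattacharyya metric sqrt(1 - BC), BC = sum_i sqrt(X^_i * Y^_i)
COS         cosine distance 1 - x.y / (|x||y|), on raw counts
==========  ====================================================================

where X^ denotes the row normalized into a probability vector, optionally
under a Gamma(beta, beta) pseudo-count prior: X^_i = (X_i + beta)/(S + d*beta)
with S the row total and d the gene count. The probability measures (KLD,
JSD, BATMET) require either an active prior or strictly positive row sums.

The prior is applied *lazily*: a prior-adjusted row is a constant baseline
beta/(S + d*beta) everywhere plus stored-entry corrections, so a pairwise
distance only touches the union of the two supports — the (d - |supp(x) u
supp(y)|) shared-zero features contribute one closed-form aggregate term.
Work and memory per pair are proportional to nnz, never to d. Natural
logarithms throughout (so 0 <= JSD <= ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.special import rel_entr

from .errors import DegenerateInputError
from .priors import Prior
from .sparse import CSRMatrix

__all__ = [
    "Measure",
    "PROBABILITY_MEASURES",
    "NormalizedView",
    "distance",
    "point_to_centers_costs",
    "total_cost",
    "MatrixContext",
    "reset_entry_count",
    "entry_count",
]


class Measure(str, Enum):
    """Dissimilarity measure identifiers (accepted case-insensitively)."""

    SQE = "SQE"
    KLD = "KLD"
    JSD = "JSD"
    BATMET = "BATMET"
    COS = "COS"

    @classmethod
    def parse(cls, name: Union[str, "Measure"]) -> "Measure":
        if isinstance(name, Measure):
            return name
        try:
            return cls[str(name).upper()]
        except KeyError:
            raise ValueError(
                f"unknown measure {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


PROBABILITY_MEASURES = frozenset({Measure.KLD, Measure.JSD, Measure.BATMET})

# --------------------------------------------------------------------------
# instrumentation: entries touched by pairwise distance evaluations.
# The complexity contract of the lazy kernel is that this grows with the
# nnz of the operands, not with the dimension d.

_ENTRY_COUNT = 0


def reset_entry_count() -> None:
    global _ENTRY_COUNT
    _ENTRY_COUNT = 0


def entry_count() -> int:
    return _ENTRY_COUNT


def _touch(n: int) -> None:
    global _ENTRY_COUNT
    _ENTRY_COUNT += int(n)


# --------------------------------------------------------------------------
# row views


@dataclass(frozen=True)
class NormalizedView:
    """A matrix row seen as a probability vector without materializing it.

    The view is the baseline value ``beta/(S + d*beta)`` on every feature,
    overridden on the row's support by ``(X_i + beta)/(S + d*beta)``; with
    no prior, baseline 0 and values ``X_i / S``. The full vector sums to 1.
    """

    idx: np.ndarray  # support column indices
    raw: np.ndarray  # raw stored values on the support
    n_cols: int
    row_sum: float
    prior: Prior

    @classmethod
    def of(cls, m: CSRMatrix, i: int, prior: Prior = None) -> "NormalizedView":
        idx, vals = m.row_support(i)
        return cls(idx=idx, raw=vals, n_cols=m.n_cols,
                   row_sum=float(vals.sum()), prior=prior)

    @property
    def norm(self) -> float:
        """Normalizer: S + d*beta with a prior, S without."""
        if self.prior is not None:
            return self.row_sum + self.n_cols * self.prior.beta
        return self.row_sum

    @property
    def baseline(self) -> float:
        """Probability assigned to each zero-count feature."""
        if self.prior is None:
            return 0.0
        return self.prior.beta / self.norm

    @property
    def support_probs(self) -> np.ndarray:
        """Probabilities at the stored entries."""
        if self.prior is not None:
            return (self.raw + self.prior.beta) / self.norm
        if self.row_sum <= 0:
            raise DegenerateInputError(
                "zero-sum row has no probability representation without a prior"
            )
        return self.raw / self.row_sum

    def densify(self) -> np.ndarray:
        """Materialize the full probability vector (testing / small d only)."""
        if self.prior is None and self.row_sum <= 0:
            raise DegenerateInputError(
                "zero-sum row has no probability representation without a prior"
            )
        out = np.full(self.n_cols, self.baseline)
        out[self.idx] = self.support_probs
        return out


_RowLike = Union[NormalizedView, Tuple[CSRMatrix, int], np.ndarray, Sequence[float]]


def _as_support(x: _RowLike, prior: Prior) -> NormalizedView:
    """Coerce a row-like input to a support representation of raw values."""
    if isinstance(x, NormalizedView):
        return x
    if isinstance(x, tuple) and len(x) == 2 and isinstance(x[0], CSRMatrix):
        return NormalizedView.of(x[0], int(x[1]), prior)
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 1:
        raise ValueError("dense row input must be 1-D")
    idx = np.flatnonzero(a)
    return NormalizedView(idx=idx, raw=a[idx], n_cols=a.size,
                          row_sum=float(a.sum()), prior=prior)


# --------------------------------------------------------------------------
# pairwise distance (sparse x sparse), O(nnz_x + nnz_y)


def distance(x: _RowLike, y: _RowLike, measure, prior: Prior = None) -> float:
    """Dissimilarity between two rows under ``measure``.

    ``x`` and ``y`` may each be a :class:`NormalizedView`, a ``(CSRMatrix,
    row_index)`` pair, or a 1-D array of raw values. Probability measures
    normalize under ``prior``; SQE and COS operate on raw values and ignore
    the prior. Only the union of the two supports is touched; shared zeros
    enter through a single closed-form term.
    """
    measure = Measure.parse(measure)
    xv = _as_support(x, prior)
    yv = _as_support(y, prior)
    if xv.n_cols != yv.n_cols:
        raise ValueError(f"dimension mismatch: {xv.n_cols} vs {yv.n_cols}")
    d = xv.n_cols

    union = np.union1d(xv.idx, yv.idx)
    nu = union.size
    _touch(xv.idx.size + yv.idx.size + nu)

    xr = np.zeros(nu)
    xr[np.searchsorted(union, xv.idx)] = xv.raw
    yr = np.zeros(nu)
    yr[np.searchsorted(union, yv.idx)] = yv.raw

    if measure is Measure.SQE:
        diff = xr - yr
        return float(diff @ diff)

    if measure is Measure.COS:
        nx = float(np.sqrt(xr @ xr))
        ny = float(np.sqrt(yr @ yr))
        if nx == 0.0 or ny == 0.0:
            return 1.0
        return float(max(0.0, 1.0 - (xr @ yr) / (nx * ny)))

    # probability measures
    if prior is not None:
        beta = prior.beta
        nx_, ny_ = xv.row_sum + d * beta, yv.row_sum + d * beta
        px = (xr + beta) / nx_
        py = (yr + beta) / ny_
        bx, by = beta / nx_, beta / ny_
    else:
        if xv.row_sum <= 0 or yv.row_sum <= 0:
            raise DegenerateInputError(
                f"{measure.value} requires a prior or strictly positive row sums"
            )
        px = xr / xv.row_sum
        py = yr / yv.row_sum
        bx = by = 0.0
    rest = d - nu  # shared-zero features, aggregated

    if measure is Measure.KLD:
        val = float(rel_entr(px, py).sum()) + rest * float(rel_entr(bx, by))
        return val

    if measure is Measure.JSD:
        m_ = 0.5 * (px + py)
        mb = 0.5 * (bx + by)
        val = 0.5 * float(rel_entr(px, m_).sum() + rel_entr(py, m_).sum())
        val += rest * 0.5 * (float(rel_entr(bx, mb)) + float(rel_entr(by, mb)))
        return val

    # BATMET
    bc = float(np.sqrt(px * py).sum()) + rest * float(np.sqrt(bx * by))
    return float(np.sqrt(max(0.0, 1.0 - bc)))


# --------------------------------------------------------------------------
# vectorized row-to-center distances


def _row_sums_of(vals: np.ndarray, m: CSRMatrix) -> np.ndarray:
    """Per-row sums of an nnz-aligned entry array (exact per-row summation)."""
    t = sp.csr_matrix((vals, m.indices, m.indptr), shape=m.shape)
    return np.asarray(t.sum(axis=1)).ravel()


class MatrixContext:
    """Precomputed per-row statistics for fast rows-to-center distances.

    Build once per (matrix, measure, prior); every seeding / clustering
    pass reuses it. All per-center work is O(nnz + d): the d part is one
    aggregate over the center's entries (its log-sum for KLD, sqrt-sum for
    BATMET, squared norm for SQE), the nnz part is a sparse matvec.
    """

    def __init__(self, m: CSRMatrix, measure, prior: Prior = None):
        self.m = m
        self.measure = Measure.parse(measure)
        self.prior = prior
        s = m.to_scipy()
        self.S = np.asarray(s.sum(axis=1)).ravel()
        self.row_nnz = np.diff(m.indptr)
        d = m.n_cols

        if self.measure in PROBABILITY_MEASURES:
            if prior is not None:
                self.N = self.S + d * prior.beta
                self.b = prior.beta / self.N
            else:
                if np.any(self.S <= 0):
                    raise DegenerateInputError(
                        f"{self.measure.value} requires a prior or strictly "
                        "positive row sums (zero-sum row present)"
                    )
                self.N = self.S.copy()
                self.b = np.zeros_like(self.S)
        if self.measure is Measure.SQE or self.measure is Measure.COS:
            self.row_sq = _row_sums_of(m.data**2, m)
            if self.measure is Measure.COS:
                self.row_l2 = np.sqrt(self.row_sq)
        if self.measure is Measure.KLD:
            beta = prior.beta if prior is not None else 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                e = (m.data + beta) * np.log(m.data + beta)
            e = np.nan_to_num(e, nan=0.0)  # 0*log(0) at beta=0
            h = _row_sums_of(e, m)
            if prior is not None:
                h = h + (d - self.row_nnz) * beta * np.log(beta)
            # sum_i p_i ln p_i per row
            self.neg_entropy = h / self.N - np.log(self.N)

    # -- working representation ------------------------------------------

    def row_vector(self, i: int) -> np.ndarray:
        """Dense working-representation vector of row ``i``.

        Raw counts for SQE, the prior-adjusted probability vector for
        KLD/JSD/BATMET, the L2-normalized vector for COS.
        """
        idx, vals = self.m.row_support(i)
        d = self.m.n_cols
        if self.measure is Measure.SQE:
            out = np.zeros(d)
            out[idx] = vals
            return out
        if self.measure is Measure.COS:
            out = np.zeros(d)
            l2 = self.row_l2[i]
            if l2 > 0:
                out[idx] = vals / l2
            return out
        return NormalizedView.of(self.m, i, self.prior).densify()

    def prob_dev_matrix(self) -> sp.csr_matrix:
        """Sparse deviations of probability rows from their baselines.

        Row i of the probability representation is b_i * 1 + dev_i with
        dev stored sparsely: dev[i, j] = X_ij / N_i on the support
        ((X+beta)/N - beta/N = X/N). Means of probability vectors reduce to
        a mean baseline plus a sparse row mean.
        """
        s = self.m.to_scipy()
        return sp.csr_matrix(
            (s.data / np.repeat(self.N, self.row_nnz), s.indices, s.indptr),
            shape=s.shape,
        )

    def scaled_rows(self) -> sp.csr_matrix:
        """Rows in the measure's working representation, sparse part only.

        For probability measures the constant baseline is *not* included
        (see :meth:`prob_dev_matrix`).
        """
        s = self.m.to_scipy()
        if self.measure is Measure.SQE:
            return s
        if self.measure is Measure.COS:
            safe = np.where(self.row_l2 > 0, self.row_l2, 1.0)
            scale = np.where(self.row_l2 > 0, 1.0 / safe, 0.0)
            return sp.csr_matrix(
                (s.data * np.repeat(scale, self.row_nnz), s.indices, s.indptr),
                shape=s.shape,
            )
        return self.prob_dev_matrix()

    def group_stats(self, assignments: np.ndarray, k: int,
                    rows: Optional[np.ndarray] = None
                    ) -> Tuple[np.ndarray, np.ndarray]:
        """Per-group sums of working-representation vectors and member counts.

        ``assignments`` is aligned with ``rows`` (all rows when ``None``).
        Returns ``(sums (k, d) dense, counts (k,))``; a group sum includes
        the aggregated baselines for probability measures, so
        ``sums[g] / counts[g]`` is the exact mean working vector.
        """
        d = self.m.n_cols
        part = self.scaled_rows()
        if rows is not None:
            rows = np.asarray(rows)
            part = part[rows]
        nb = part.shape[0]
        assignments = np.asarray(assignments)
        onehot = sp.csr_matrix(
            (np.ones(nb), (assignments, np.arange(nb))), shape=(k, nb)
        )
        sums = (onehot @ part).toarray()
        counts = np.bincount(assignments, minlength=k).astype(np.float64)
        if self.measure in PROBABILITY_MEASURES:
            b = self.b if rows is None else self.b[rows]
            bsum = np.bincount(assignments, weights=b, minlength=k)
            sums = sums + bsum[:, None]
        return sums, counts

    def finalize_center(self, vec: np.ndarray) -> np.ndarray:
        """Post-process a mean vector into a valid center for the measure."""
        if self.measure is Measure.COS:
            n = np.linalg.norm(vec)
            return vec / n if n > 0 else vec
        return vec

    # -- distances ---------------------------------------------------------

    def distances_to_center(self, c: np.ndarray,
                            rows: Optional[np.ndarray] = None) -> np.ndarray:
        """Distances from every row (or a row subset) to one dense center.

        The center must be in the measure's working representation.
        """
        c = np.asarray(c, dtype=np.float64)
        s = self.m.to_scipy()
        if rows is not None:
            rows = np.asarray(rows)
            s = s[rows]
        meas = self.measure

        if meas is Measure.SQE:
            row_sq = self.row_sq if rows is None else self.row_sq[rows]
            out = row_sq - 2.0 * (s @ c) + float(c @ c)
            return np.maximum(out, 0.0)

        if meas is Measure.COS:
            l2 = self.row_l2 if rows is None else self.row_l2[rows]
            cn = float(np.linalg.norm(c))
            out = np.ones(s.shape[0])
            if cn > 0:
                ok = l2 > 0
                dots = s @ c
                out[ok] = 1.0 - dots[ok] / (l2[ok] * cn)
            return np.maximum(out, 0.0)

        N = self.N if rows is None else self.N[rows]
        b = self.b if rows is None else self.b[rows]
        nnz_r = self.row_nnz if rows is None else self.row_nnz[rows]
        d = self.m.n_cols

        if meas is Measure.KLD:
            neg_ent = self.neg_entropy if rows is None else self.neg_entropy[rows]
            with np.errstate(divide="ignore"):
                lnc = np.log(c)
            # sum_i p_i ln c_i = (X @ ln c)/N + b * sum_i ln c_i
            cross = (s @ lnc) / N + b * float(lnc.sum())
            out = neg_ent - cross
            return np.maximum(np.nan_to_num(out, nan=np.inf), 0.0)

        if meas is Measure.BATMET:
            sqc = np.sqrt(c)
            qc = float(sqc.sum())
            beta = self.prior.beta if self.prior is not None else 0.0
            # per-entry sqrt((X+beta) * c_j), summed per row
            ent = np.sqrt((s.data + beta) * c[s.indices])
            t = sp.csr_matrix((ent, s.indices, s.indptr), shape=s.shape)
            supp_bc = np.asarray(t.sum(axis=1)).ravel() / np.sqrt(N)
            # support sum of sqrt(c)
            t2 = sp.csr_matrix((sqc[s.indices], s.indices, s.indptr), shape=s.shape)
            supp_sqc = np.asarray(t2.sum(axis=1)).ravel()
            bc = supp_bc + np.sqrt(b) * (qc - supp_sqc)
            return np.sqrt(np.maximum(0.0, 1.0 - bc))

        # JSD: the off-support terms couple the row baseline with every center
        # entry, so there is no per-center closed form; evaluate exactly on
        # densified row blocks (memory-bounded).
        return self._jsd_to_center(s, c, N, b)

    def _jsd_to_center(self, s: sp.csr_matrix, c: np.ndarray,
                       N: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = self.m.n_cols
        n = s.shape[0]
        beta = self.prior.beta if self.prior is not None else 0.0
        out = np.empty(n)
        block = max(1, int(4_000_000 // max(d, 1)))
        for lo in range(0, n, block):
            hi = min(lo + block, n)
            sub = s[lo:hi]
            p = np.repeat(b[lo:hi, None], d, axis=1)
            r = sub.tocoo()
            p[r.row, r.col] = (r.data + beta) / N[lo + r.row]
            m_ = 0.5 * (p + c[None, :])
            out[lo:hi] = 0.5 * (
                rel_entr(p, m_).sum(axis=1) + rel_entr(c[None, :], m_).sum(axis=1)
            )
        return np.maximum(out, 0.0)


def point_to_centers_costs(
    m: CSRMatrix,
    centers: np.ndarray,
    measure,
    prior: Prior = None,
    ctx: Optional[MatrixContext] = None,
    rows: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Min cost and argmin center index per row; ties go to the lower index.

    ``centers`` is a (k, d) array in the measure's working representation.
    """
    if ctx is None:
        ctx = MatrixContext(m, measure, prior)
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    n = m.n_rows if rows is None else len(rows)
    best = np.full(n, np.inf)
    arg = np.zeros(n, dtype=np.int64)
    for j in range(centers.shape[0]):
        dj = ctx.distances_to_center(centers[j], rows=rows)
        better = dj < best  # strict: ties keep the lower center index
        best[better] = dj[better]
        arg[better] = j
    return best, arg


def total_cost(costs: np.ndarray) -> float:
    """Objective value: sum of per-row minimum costs."""
    return float(np.sum(costs))
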
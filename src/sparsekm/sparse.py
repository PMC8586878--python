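"""Canonical compressed-sparse-row count matrices and per-row cached statistics.

Every stage of the pipeline consumes a :class:`CSRMatrix`: a validated,
canonical CSR matrix of nonnegative counts (cells as rows, genes as columns).
Canonical means: indices sorted strictly increasing within each row, no
explicit zeros, no duplicate entries.

:class:`RowCache` holds the per-row totals needed to normalize a row into a
probability vector under a pseudo-count prior without densifying it:
for row with total S over d genes and prior beta, the normalizer is
S + d*beta and each count X_i maps to (X_i + beta) / (S + d*beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .priors import Prior

__all__ = [
    "CSRMatrix",
    "RowCache",
    "validate",
    "build_row_cache",
    "select_top_variable_genes",
]


class CSRMatrix:
    """A validated, canonical CSR matrix of nonnegative values.

    Thin wrapper over :class:`scipy.sparse.csr_matrix` that enforces the
    package's invariants at construction time:

    * ``indptr[0] == 0``, ``indptr[-1] == nnz``, ``indptr`` nondecreasing;
    * within each row, column indices strictly increasing, all in
      ``[0, n_cols)``;
    * all stored values >= 0; explicit zeros and duplicates are removed
      (duplicates are summed first, matching coordinate-format semantics).

    ``dtype_kind`` is ``"integer"`` when the source data was an integer
    count matrix and ``"real"`` otherwise; divergence math always promotes
    to float64.
    """

    __slots__ = ("_sp", "dtype_kind")

    def __init__(self, data, indices, indptr, shape: Tuple[int, int]):
        data = np.asarray(data)
        indices = np.asarray(indices)
        indptr = np.asarray(indptr)
        if indptr.ndim != 1 or data.ndim != 1 or indices.ndim != 1:
            raise ValidationError("data, indices and indptr must be 1-D arrays")
        n_rows, n_cols = int(shape[0]), int(shape[1])
        if n_rows < 0 or n_cols < 0:
            raise ValidationError(f"invalid shape {shape}")
        if len(indptr) != n_rows + 1:
            raise ValidationError(
                f"indptr has length {len(indptr)}, expected n_rows+1 = {n_rows + 1}"
            )
        if len(data) != len(indices):
            raise ValidationError("data and indices lengths differ")
        if indptr[0] != 0 or indptr[-1] != len(data):
            raise ValidationError("indptr must start at 0 and end at nnz")
        if np.any(np.diff(indptr) < 0):
            raise ValidationError("indptr must be nondecreasing")
        if len(indices) and (indices.min() < 0 or indices.max() >= n_cols):
            raise ValidationError("column index out of range")
        if len(data) and np.nanmin(data) < 0:
            raise ValidationError("negative values are not allowed")
        if np.issubdtype(data.dtype, np.floating) and np.any(~np.isfinite(data)):
            raise ValidationError("non-finite values are not allowed")

        self.dtype_kind = (
            "integer" if np.issubdtype(data.dtype, np.integer) else "real"
        )
        m = sp.csr_matrix(
            (data.astype(np.float64), indices.astype(np.int64), indptr.astype(np.int64)),
            shape=(n_rows, n_cols),
        )
        # canonical form: duplicates summed, indices sorted, explicit zeros dropped
        m.sum_duplicates()
        m.sort_indices()
        m.eliminate_zeros()
        self._sp = m

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_scipy(cls, m, dtype_kind: Optional[str] = None) -> "CSRMatrix":
        """Build from any scipy sparse matrix (converted to CSR)."""
        m = sp.csr_matrix(m)
        kind = dtype_kind
        if kind is None:
            kind = "integer" if np.issubdtype(m.dtype, np.integer) else "real"
        out = cls(m.data, m.indices, m.indptr, m.shape)
        out.dtype_kind = kind
        return out

    @classmethod
    def from_dense(cls, a) -> "CSRMatrix":
        """Build from a dense 2-D array."""
        a = np.asarray(a)
        kind = "integer" if np.issubdtype(a.dtype, np.integer) else "real"
        return cls.from_scipy(sp.csr_matrix(a), dtype_kind=kind)

    # -- views -------------------------------------------------------------

    def to_scipy(self) -> sp.csr_matrix:
        """The underlying scipy CSR matrix (float64, canonical). Do not mutate."""
        return self._sp

    def to_dense(self) -> np.ndarray:
        return self._sp.toarray()

    @property
    def n_rows(self) -> int:
        return self._sp.shape[0]

    @property
    def n_cols(self) -> int:
        return self._sp.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self._sp.shape

    @property
    def nnz(self) -> int:
        return self._sp.nnz

    @property
    def data(self) -> np.ndarray:
        return self._sp.data

    @property
    def indices(self) -> np.ndarray:
        return self._sp.indices

    @property
    def indptr(self) -> np.ndarray:
        return self._sp.indptr

    def row_support(self, i: int) -> Tuple[np.ndarray, np.ndarray]:
        """(column indices, values) of row i's stored entries."""
        lo, hi = self._sp.indptr[i], self._sp.indptr[i + 1]
        return self._sp.indices[lo:hi], self._sp.data[lo:hi]

    def select_rows(self, rows) -> "CSRMatrix":
        return CSRMatrix.from_scipy(self._sp[np.asarray(rows)], dtype_kind=self.dtype_kind)

    def select_columns(self, cols) -> "CSRMatrix":
        return CSRMatrix.from_scipy(self._sp[:, np.asarray(cols)], dtype_kind=self.dtype_kind)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CSRMatrix({self.n_rows}x{self.n_cols}, nnz={self.nnz}, "
            f"dtype_kind={self.dtype_kind!r})"
        )


def validate(m) -> CSRMatrix:
    """Return a canonicalized :class:`CSRMatrix` or raise :class:`ValidationError`.

    Accepts a CSRMatrix (re-canonicalized; a fixed point), a scipy sparse
    matrix, or a dense 2-D array. Sorting, duplicate summation and explicit
    zero removal are applied; negative values, out-of-range indices and
    malformed indptr raise.
    """
    if isinstance(m, CSRMatrix):
        out = CSRMatrix(m.data, m.indices, m.indptr, m.shape)
        out.dtype_kind = m.dtype_kind
        return out
    if sp.issparse(m):
        c = m.tocsr(copy=True)
        if c.nnz and c.data.min() < 0:
            raise ValidationError("negative values are not allowed")
        return CSRMatrix.from_scipy(c)
    a = np.asarray(m)
    if a.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if a.size and a.min() < 0:
        raise ValidationError("negative values are not allowed")
    return CSRMatrix.from_dense(a)


@dataclass(frozen=True)
class RowCache:
    """Per-row totals supporting O(nnz) prior-adjusted normalization.

    Attributes
    ----------
    row_sum : total count S of each row (exact sum of stored entries).
    row_nnz : number of stored entries of each row.
    prior_norm : S + d*beta per row when a prior is active, else ``None``.
        This is the denominator turning posterior counts X_i + beta into
        probabilities.
    """

    row_sum: np.ndarray
    row_nnz: np.ndarray
    prior_norm: Optional[np.ndarray]


def build_row_cache(m: CSRMatrix, prior: Prior = None) -> RowCache:
    """Compute per-row sums, nnz and (when a prior is active) normalizers."""
    s = np.asarray(m.to_scipy().sum(axis=1)).ravel().astype(np.float64)
    nnz = np.diff(m.indptr).astype(np.int64)
    norm = None
    if prior is not None:
        norm = s + m.n_cols * prior.beta
        if np.any(norm <= 0):
            raise ValidationError("prior normalizer must be positive")
    return RowCache(row_sum=s, row_nnz=nnz, prior_norm=norm)


def gene_variances(m: CSRMatrix) -> np.ndarray:
    """Per-gene (column) variance of raw counts over all cells, sparse-aware.

    Population variance E[X^2] - E[X]^2 computed from column sums of the
    values and their squares; zero columns have variance 0.
    """
    s = m.to_scipy()
    n = m.n_rows
    if n == 0:
        return np.zeros(m.n_cols)
    col_sum = np.asarray(s.sum(axis=0)).ravel()
    sq = s.copy()
    sq.data = sq.data**2
    col_sq = np.asarray(sq.sum(axis=0)).ravel()
    mean = col_sum / n
    var = col_sq / n - mean**2
    return np.maximum(var, 0.0)


def select_top_variable_genes(
    m: CSRMatrix, n_top: int
) -> Tuple[np.ndarray, CSRMatrix]:
    """Keep the ``n_top`` genes with largest raw-count variance.

    Ties are broken toward the lower column index; selected columns are
    returned in ascending column order (row order is preserved). Returns
    ``(column indices, column-sliced matrix)``.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    if n_top > m.n_cols:
        raise ValueError(f"n_top={n_top} exceeds n_cols={m.n_cols}")
    var = gene_variances(m)
    # stable sort on -var keeps lower indices first among ties
    order = np.argsort(-var, kind="stable")[:n_top]
    cols = np.sort(order)
    return cols, m.select_columns(cols)
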
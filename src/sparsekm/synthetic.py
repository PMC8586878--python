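"""Planted-mixture generators for sparse count matrices.

Each cell (row) is drawn as Multinomial(total_i, p_c) where p_c is the
gene-probability vector of its cluster, mirroring the sampling view of
sequencing counts that the probability-based divergences assume. Cluster
profiles are Dirichlet draws whose concentration ``alpha`` acts as the
separation knob: small alpha gives peaked, nearly disjoint profiles (easy
to cluster), large alpha gives near-uniform, overlapping ones (hard).
An optional row-level Dirichlet resampling adds overdispersion beyond the
multinomial, and ``disjoint=True`` plants clusters on disjoint gene blocks
(the infinitely-separated limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .sparse import CSRMatrix, validate

__all__ = ["MixtureSpec", "generate", "sparsify_stats"]


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of a planted multinomial mixture.

    n_per_cluster : rows per cluster (an int, or one count per cluster).
    n_cols        : number of genes d.
    k_true        : number of planted clusters.
    alpha         : Dirichlet concentration of the cluster profiles
                    (separation knob; smaller = better separated).
    total_counts  : per-row total count (library size).
    total_sigma   : lognormal sigma of the library size (0 = fixed totals).
    disjoint      : plant each cluster on its own gene block.
    overdispersion: if > 0, each row re-draws its probabilities from
                    Dirichlet(overdispersion * p_cluster * d); smaller
                    values mean more extra-multinomial noise.
    seed          : generator seed (byte-identical output per seed).
    """

    n_per_cluster: Union[int, Sequence[int]] = 100
    n_cols: int = 200
    k_true: int = 5
    alpha: float = 0.1
    total_counts: int = 500
    total_sigma: float = 0.0
    disjoint: bool = False
    overdispersion: float = 0.0
    seed: int = 0

    def cluster_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_cluster):
            return np.full(self.k_true, int(self.n_per_cluster), dtype=np.int64)
        sizes = np.asarray(self.n_per_cluster, dtype=np.int64)
        if sizes.size != self.k_true:
            raise ValueError("n_per_cluster must have k_true entries")
        return sizes

    def __post_init__(self):
        if self.k_true < 1 or self.n_cols < 1:
            raise ValueError("k_true and n_cols must be positive")
        if self.alpha <= 0 or self.total_counts < 1:
            raise ValueError("alpha and total_counts must be positive")
        if np.any(self.cluster_sizes() < 1):
            raise ValueError("every cluster needs at least one row")


def _cluster_profiles(spec: MixtureSpec, rng: np.random.Generator) -> np.ndarray:
    d, k = spec.n_cols, spec.k_true
    if spec.disjoint:
        if d < k:
            raise ValueError("disjoint clusters need n_cols >= k_true")
        probs = np.zeros((k, d))
        edges = np.linspace(0, d, k + 1).astype(int)
        for c in range(k):
            block = slice(edges[c], edges[c + 1])
            width = edges[c + 1] - edges[c]
            probs[c, block] = rng.dirichlet(np.full(width, 1.0))
        return probs
    return rng.dirichlet(np.full(d, spec.alpha), size=k)


def generate(spec: MixtureSpec) -> Tuple[CSRMatrix, np.ndarray]:
    """Draw the planted mixture; returns (canonical CSR matrix, labels)."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    sizes = spec.cluster_sizes()
    profiles = _cluster_profiles(spec, rng)
    blocks = []
    labels = []
    for c, n_c in enumerate(sizes):
        if spec.total_sigma > 0:
            totals = np.maximum(
                1,
                np.round(
                    rng.lognormal(np.log(spec.total_counts), spec.total_sigma, n_c)
                ).astype(np.int64),
            )
        else:
            totals = np.full(n_c, spec.total_counts, dtype=np.int64)
        if spec.overdispersion > 0:
            conc = spec.overdispersion * profiles[c] * spec.n_cols
            conc = np.maximum(conc, 1e-12)
            rows = np.stack(
                [rng.multinomial(t, rng.dirichlet(conc)) for t in totals]
            )
        elif spec.total_sigma > 0:
            rows = np.stack([rng.multinomial(t, profiles[c]) for t in totals])
        else:
            rows = rng.multinomial(spec.total_counts, profiles[c], size=n_c)
        blocks.append(sp.csr_matrix(rows))
        labels.extend([c] * int(n_c))
    mat = validate(sp.vstack(blocks).tocsr())
    mat.dtype_kind = "integer"
    return mat, np.asarray(labels, dtype=np.int64)


def sparsify_stats(m: CSRMatrix) -> Dict:
    """Density and the per-row nnz distribution of a matrix (reporting only)."""
    row_nnz = np.diff(m.indptr)
    total = m.n_rows * m.n_cols
    return {
        "n_rows": m.n_rows,
        "n_cols": m.n_cols,
        "nnz": int(m.nnz),
        "density": (m.nnz / total) if total else 0.0,
        "row_nnz_min": int(row_nnz.min()) if m.n_rows else 0,
        "row_nnz_median": float(np.median(row_nnz)) if m.n_rows else 0.0,
        "row_nnz_max": int(row_nnz.max()) if m.n_rows else 0,
        "row_nnz_mean": float(row_nnz.mean()) if m.n_rows else 0.0,
    }
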
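"""Readers and writers for the formats the tool touches.

* Matrix Market coordinate files (``.mtx``, real/integer, general
  symmetry) via scipy.io; 1-based file indices become 0-based internally.
* A raw binary CSR triple (flat ``data`` / ``indices`` / ``indptr``
  arrays) described by a small JSON sidecar holding the shape and dtype
  codes — the triple alone is ambiguous without them. Narrow integer
  fields (e.g. 16-bit) are accepted and widened.
* Labels (one per line) and assignment tables as TSV.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import UnsupportedFormat, ValidationError
from .sparse import CSRMatrix, validate

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_csr_binary",
    "write_csr_binary",
    "read_labels",
    "write_assignments",
    "write_centers",
]

PathLike = Union[str, os.PathLike]


def read_mtx(path: PathLike) -> CSRMatrix:
    """Read a Matrix Market coordinate file into a canonical CSR matrix."""
    path = Path(path)
    try:
        rows, cols, entries, fmt, field, symm = scipy.io.mminfo(path)
    except ValueError as e:
        raise UnsupportedFormat(f"not a readable Matrix Market file: {e}") from e
    if field in ("pattern", "complex"):
        raise UnsupportedFormat(f"Matrix Market field {field!r} is not supported")
    if symm != "general":
        raise UnsupportedFormat(f"symmetry {symm!r} is not supported")
    m = scipy.io.mmread(path)
    if sp.issparse(m):
        m = m.tocsr()
    else:
        m = sp.csr_matrix(np.asarray(m))
    if m.nnz and m.data.min() < 0:
        raise ValidationError("negative entries are not allowed")
    return validate(m)


def write_mtx(m: CSRMatrix, path: PathLike) -> None:
    """Write coordinate Matrix Market (1-based, row-major sorted, lossless)."""
    s = m.to_scipy().tocoo()
    if m.dtype_kind == "integer":
        s = s.astype(np.int64)
    scipy.io.mmwrite(Path(path), s, field=None, precision=17, symmetry="general")


_DTYPE_CODES = {
    "u1": np.uint8, "u2": np.uint16, "u4": np.uint32, "u8": np.uint64,
    "i1": np.int8, "i2": np.int16, "i4": np.int32, "i8": np.int64,
    "f4": np.float32, "f8": np.float64,
}


def write_csr_binary(m: CSRMatrix, prefix: PathLike) -> Path:
    """Write the data/indices/indptr triple plus a JSON sidecar.

    Files written: ``<prefix>.data.bin``, ``<prefix>.indices.bin``,
    ``<prefix>.indptr.bin`` and ``<prefix>.json``; returns the sidecar path.
    """
    prefix = Path(prefix)
    data = m.data
    if m.dtype_kind == "integer":
        data = data.astype(np.int64)
    arrays = {
        "data": np.ascontiguousarray(data),
        "indices": np.ascontiguousarray(m.indices.astype(np.int64)),
        "indptr": np.ascontiguousarray(m.indptr.astype(np.int64)),
    }
    sidecar = {
        "shape": [m.n_rows, m.n_cols],
        "nnz": int(m.nnz),
        "files": {},
        "dtypes": {},
    }
    for name, arr in arrays.items():
        fname = f"{prefix.name}.{name}.bin"
        arr.tofile(prefix.parent / fname)
        sidecar["files"][name] = fname
        sidecar["dtypes"][name] = arr.dtype.str.lstrip("<>=|")
    out = prefix.parent / f"{prefix.name}.json"
    out.write_text(json.dumps(sidecar, indent=1))
    return out


def read_csr_binary(sidecar_path: PathLike) -> CSRMatrix:
    """Read a binary CSR triple described by its JSON sidecar.

    The sidecar must provide ``shape``, per-array file names and dtype
    codes (u2/i4/f8 style). Narrow fields are widened on load. Length or
    indptr/shape mismatches raise :class:`ValidationError`.
    """
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    try:
        shape = tuple(int(x) for x in meta["shape"])
        files = meta["files"]
        dtypes = meta["dtypes"]
    except KeyError as e:
        raise ValidationError(f"sidecar missing key: {e}") from e
    arrays = {}
    for name in ("data", "indices", "indptr"):
        code = dtypes[name]
        if code not in _DTYPE_CODES:
            raise ValidationError(f"unknown dtype code {code!r} for {name}")
        arrays[name] = np.fromfile(
            sidecar_path.parent / files[name], dtype=_DTYPE_CODES[code]
        )
    n_rows = shape[0]
    if arrays["indptr"].size != n_rows + 1:
        raise ValidationError(
            f"indptr length {arrays['indptr'].size} does not match shape {shape}"
        )
    if arrays["data"].size != arrays["indices"].size:
        raise ValidationError("data and indices lengths differ (truncated file?)")
    if arrays["indptr"].size and arrays["indptr"][-1] != arrays["data"].size:
        raise ValidationError("indptr[-1] does not equal nnz (truncated file?)")
    return validate(
        CSRMatrix(arrays["data"], arrays["indices"], arrays["indptr"], shape)
    )


def read_labels(path: PathLike, n_rows: Optional[int] = None) -> np.ndarray:
    """One label per line; validated against ``n_rows`` when given."""
    lines = Path(path).read_text().splitlines()
    labels = np.asarray([ln.strip() for ln in lines if ln.strip() != ""])
    if n_rows is not None and labels.size != n_rows:
        raise ValidationError(
            f"label file has {labels.size} labels for {n_rows} matrix rows"
        )
    return labels


def write_labels(labels: Sequence, path: PathLike) -> None:
    Path(path).write_text("".join(f"{l}\n" for l in labels))


def write_assignments(
    assignments: Sequence[int], costs: Sequence[float], path: PathLike
) -> None:
    """TSV with header: row_id, cluster_id, cost."""
    assignments = np.asarray(assignments)
    costs = np.asarray(costs, dtype=np.float64)
    if assignments.size != costs.size:
        raise ValidationError("assignments and costs lengths differ")
    with open(path, "w") as fh:
        fh.write("row_id\tcluster_id\tcost\n")
        for i, (a, c) in enumerate(zip(assignments, costs)):
            fh.write(f"{i}\t{int(a)}\t{c:.17g}\n")


def read_assignments(path: PathLike):
    """Inverse of :func:`write_assignments`; returns (assignments, costs)."""
    rows = Path(path).read_text().splitlines()
    if not rows or rows[0].split("\t") != ["row_id", "cluster_id", "cost"]:
        raise ValidationError("missing assignments header")
    assign, costs = [], []
    for ln in rows[1:]:
        _, a, c = ln.split("\t")
        assign.append(int(a))
        costs.append(float(c))
    return np.asarray(assign, dtype=np.int64), np.asarray(costs)


def write_centers(centers: np.ndarray, path: PathLike) -> None:
    """Dense center vectors, one per line, tab-separated."""
    np.savetxt(path, np.atleast_2d(centers), delimiter="\t", fmt="%.17g")
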
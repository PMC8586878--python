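"""Reading and writing the supported on-disk formats.

A fixture is written as Matrix Market plus a labels TSV, read back, and
also round-tripped through the raw binary CSR triple (data / indices /
indptr arrays plus a JSON sidecar recording shape and dtypes).
"""

import tempfile
from pathlib import Path

import numpy as np

from sparsekm import (
    MixtureSpec,
    generate,
    read_csr_binary,
    read_labels,
    read_mtx,
    write_csr_binary,
    write_labels,
    write_mtx,
)

m, labels = generate(MixtureSpec(n_per_cluster=25, n_cols=60, k_true=3, seed=0))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_mtx(m, tmp / "cells.mtx")
    write_labels(labels, tmp / "cells.labels.tsv")
    m2 = read_mtx(tmp / "cells.mtx")
    l2 = read_labels(tmp / "cells.labels.tsv", n_rows=m2.n_rows)
    print("Matrix Market round trip:",
          "lossless" if np.array_equal(m.to_dense(), m2.to_dense()) else "FAILED")
    print("  file size:", (tmp / "cells.mtx").stat().st_size, "bytes for",
          m.nnz, "entries")

    sidecar = write_csr_binary(m, tmp / "cells")
    m3 = read_csr_binary(sidecar)
    print("binary CSR round trip:",
          "lossless" if np.array_equal(m.to_dense(), m3.to_dense()) else "FAILED")
    print("  sidecar:", sidecar.read_text().replace("\n", " ")[:120], "...")
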
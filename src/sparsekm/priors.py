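"""Pseudo-count prior configuration.

Count vectors from sequencing experiments are sparse: most genes have zero
observed counts in most cells. Probability-based divergences (KL, JS,
Bhattacharyya) are undefined or infinite on zero entries, so counts are
smoothed with a Gamma(beta, beta) prior: the posterior estimate of each
count is N_i + beta, which after normalization gives a strictly positive
probability vector. beta = 1 is the Dirichlet (Laplace / add-one) case;
smaller values penalize unobserved genes less aggressively.

The prior is never materialized: divergence code handles the (d - nnz)
zero-count features of each row in aggregate, keeping work O(nnz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class PriorConfig:
    """A Gamma(beta, beta) pseudo-count prior with beta > 0.

    Use ``PriorConfig(beta)`` for an active prior and ``None`` wherever a
    prior is optional (the no-prior sentinel).
    """

    beta: float

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise ValueError(f"prior beta must be > 0, got {self.beta!r}")

    @property
    def is_dirichlet(self) -> bool:
        """beta = 1 corresponds to a Dirichlet (add-one) prior."""
        return self.beta == 1.0


Prior = Optional[PriorConfig]


def beta_of(prior: Prior) -> float:
    """beta of an active prior, 0.0 for the no-prior sentinel."""
    return prior.beta if prior is not None else 0.0
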
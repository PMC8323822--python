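"""Binary connectivity and grid-frequency matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConnectivityMatrix", "FrequencyMatrix"]


@dataclass
class ConnectivityMatrix:
    """Directed binary adjacency: entries[j, k] = 1 means an inferred j -> k
    connection.  The diagonal is structurally zero (self-connections are
    never inferred because only unordered pairs j < k are correlated)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=int)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("entries must be binary")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        self.entries = m

    @property
    def n_neurons(self) -> int:
        return self.entries.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.entries.sum())

    def edge_set(self) -> set[tuple[int, int]]:
        src, dst = np.nonzero(self.entries)
        return set(zip(src.tolist(), dst.tolist()))


@dataclass
class FrequencyMatrix:
    """Per-edge occurrence frequency f_jk across the K parameter-grid points.

    f_jk = (1/K) sum_p M_p[j, k]; every entry is a multiple of 1/K in [0, 1]
    and the diagonal is zero.
    """

    entries: np.ndarray
    K: int

    def __post_init__(self) -> None:
        f = np.asarray(self.entries, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("frequency matrix must be square")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if f.min() < 0 or f.max() > 1:
            raise ValueError("frequencies must lie in [0, 1]")
        scaled = f * self.K
        if not np.allclose(scaled, np.round(scaled), atol=1e-9):
            raise ValueError("every frequency must be a multiple of 1/K")
        if np.any(np.diag(f) != 0):
            raise ValueError("diagonal must be zero")
        self.entries = f

    @property
    def n_neurons(self) -> int:
        return self.entries.shape[0]
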
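"""Maximum-weight balanced bipartite assignment (Hungarian-method core).

The solver delegates to :func:`scipy.optimize.linear_sum_assignment`,
which implements a cubic-time variant of the Kuhn-Munkres algorithm.
:func:`pad_with_sinks` turns an unbalanced case-control weight matrix
into a square one by appending zero-weight "sink" rows or columns; the
individuals matched to sinks are the ones dropped by pairwise matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class Assignment:
    """A perfect matching of rows to columns with its total weight."""

    pairs: tuple[tuple[int, int], ...]
    total_weight: float

    def column_of(self, row: int) -> int:
        for r, c in self.pairs:
            if r == row:
                return c
        raise KeyError(row)


def solve_max_assignment(weights: np.ndarray) -> Assignment:
    """Perfect matching of a square matrix maximising the summed weight."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.isfinite(w).all():
        raise ValueError("weight matrix must be finite")
    rows, cols = linear_sum_assignment(w, maximize=True)
    total = float(w[rows, cols].sum())
    return Assignment(pairs=tuple(zip(rows.tolist(), cols.tolist())), total_weight=total)


def pad_with_sinks(weights: np.ndarray) -> tuple[np.ndarray, set[int], set[int]]:
    """Square an |A| x |O| weight matrix with zero-weight sinks.

    Returns the squared matrix together with the sets of sink row and
    sink column indices (one of the two is always empty).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] == 0 or w.shape[1] == 0:
        raise ValueError("need a non-empty 2-D weight matrix")
    if (w < 0).any():
        raise ValueError("sink padding assumes nonnegative weights")
    n_rows, n_cols = w.shape
    n = max(n_rows, n_cols)
    out = np.zeros((n, n), dtype=float)
    out[:n_rows, :n_cols] = w
    sink_rows = set(range(n_rows, n))
    sink_cols = set(range(n_cols, n))
    return out, sink_rows, sink_cols
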
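"""Iterative-correction matrix balancing (plumbing only).

Region calling runs on raw sum-scaled maps; this balancer is provided for
users who want balanced matrices for display or pileup sensitivity checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["iterative_correction"]


def iterative_correction(
    matrix: np.ndarray, n_iter: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a symmetric non-negative matrix so all non-empty rows sum equally.

    Returns (balanced matrix, per-bin bias vector b) with
    ``balanced[i, j] = matrix[i, j] / (b[i] * b[j])``.  All-zero rows are left
    untouched (bias NaN).  Stops when the relative spread of non-empty row
    sums drops below ``tol``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if (m < 0).any() or not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric and non-negative")
    work = m.copy()
    nonempty = work.sum(axis=0) > 0
    bias = np.ones(m.shape[0])
    for _ in range(n_iter):
        s = work.sum(axis=0)
        s_ne = s[nonempty]
        target = s_ne.mean()
        if target == 0:
            break
        if (np.abs(s_ne / target - 1.0)).max() < tol:
            break
        adj = np.ones_like(s)
        adj[nonempty] = s_ne / target
        work = work / adj[:, None] / adj[None, :]
        bias = bias * adj
    bias_out = np.where(nonempty, bias, np.nan)
    return work, bias_out
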
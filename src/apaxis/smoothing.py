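"""Locally weighted regression (loess) as an explicit linear smoother.

Loess with a fixed design is linear in the response: the fitted value at an
evaluation point is a fixed weighted combination of the observations.
Materializing that smoother matrix once lets genome-wide profiling smooth
every gene with a single matrix product instead of refitting per gene.

Defaults follow the common loess convention: local quadratic fits with
tricube weights over the ``span`` fraction of nearest points.
"""

from __future__ import annotations

import numpy as np


def loess_matrix(
    x: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.05,
    degree: int = 2,
) -> np.ndarray:
    """Smoother matrix L with shape (len(x_eval), len(x)): fit = L @ y.

    For each evaluation point, the ``span`` fraction of nearest observations
    (at least ``degree + 2``) receive tricube weights and a weighted
    polynomial of the given degree is fitted; the row of L reproduces its
    value at the evaluation point.
    """
    x = np.asarray(x, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate positions: all x identical")
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)

    order = np.argsort(x, kind="stable")
    xs = x[order]
    L = np.zeros((x_eval.size, n))
    for j, e in enumerate(x_eval):
        # window of the k nearest points in the sorted sequence
        pos = np.searchsorted(xs, e)
        lo = max(0, pos - k)
        hi = min(n, pos + k)
        cand = np.arange(lo, hi)
        d = np.abs(xs[cand] - e)
        sel = cand[np.argsort(d, kind="stable")[:k]]
        sel.sort()
        d = np.abs(xs[sel] - e)
        h = d.max()
        if h == 0.0:
            w = np.ones(sel.size)
        else:
            w = (1.0 - np.minimum(d / (h * (1.0 + 1e-9)), 1.0) ** 3) ** 3
        deg = degree
        while np.count_nonzero(w > 0) < deg + 1 and deg > 0:
            deg -= 1
        t = xs[sel] - e
        Z = np.vander(t, N=deg + 1, increasing=True)
        WZ = Z * w[:, None]
        A = Z.T @ WZ
        # l-row: first row of (Z' W Z)^-1 Z' W
        try:
            beta_map = np.linalg.solve(A, WZ.T)
        except np.linalg.LinAlgError:
            beta_map = np.linalg.pinv(A) @ WZ.T
        L[j, order[sel]] = beta_map[0]
    return L


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Convenience wrapper: smoothed values of y(x) at x_eval."""
    return loess_matrix(x, x_eval, span=span, degree=degree) @ np.asarray(y, dtype=float)
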
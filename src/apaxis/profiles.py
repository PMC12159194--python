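"""Smoothed 80-position expression profiles along the reconstructed axis.

Nuclei close to the axis curve are selected, their positions are mirrored at
both termini (suppressing the boundary bias loess suffers where data end),
each gene's expression is loess-smoothed on a 160-point grid spanning the
mirrored range, and the central 80 points (indices 41-120) — covering
exactly the terminus-to-terminus axis — become the gene's profile,
subdivision 1 anterior to subdivision 80 posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import NormalizedMatrix
from .smoothing import loess_matrix


@dataclass
class SmoothingParams:
    near_axis_threshold: float = 0.3  # embedding units; re-tune per embedding
    span: float = 0.05  # loess span, fraction of (doubled) points
    grid_size: int = 160
    trim_lo: int = 41  # 1-based, inclusive
    trim_hi: int = 120
    degree: int = 2
    min_points: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.span <= 1.0):
            raise ValueError("span must be in (0, 1]")
        if self.trim_hi - self.trim_lo + 1 != self.grid_size // 2:
            raise ValueError("trim window length must equal grid_size / 2")

    @property
    def n_profile(self) -> int:
        return self.trim_hi - self.trim_lo + 1


def _termini(pos: pd.DataFrame, a: float | None, b: float | None) -> tuple[float, float]:
    if a is None:
        a = pos.attrs.get("anterior_terminus", float(pos["position"].min()))
    if b is None:
        b = pos.attrs.get("posterior_terminus", float(pos["position"].max()))
    if not a < b:
        raise ValueError("anterior terminus must precede posterior terminus")
    return float(a), float(b)


def select_near_axis(pos: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Keep nuclei within ``threshold`` of the curve (inclusive), in order."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = pos[pos["distance"] <= threshold].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(
            f"no nuclei within {threshold} of the axis "
            f"(closest is {pos['distance'].min():.3g}; {len(pos)} candidates)"
        )
    out.attrs.update(pos.attrs)
    return out


def mirror_positions(
    pos: pd.DataFrame, a: float | None = None, b: float | None = None
) -> pd.DataFrame:
    """Reflect the anterior half at the anterior terminus and the posterior
    half at the posterior terminus; output has exactly 2x the input rows.

    With termini a < b and midpoint c = (a+b)/2, a nucleus at p <= c gains a
    copy at 2a - p and one at p > c a copy at 2b - p, so the doubled
    positions span [2a - c, 2b - c].
    """
    a, b = _termini(pos, a, b)
    c = 0.5 * (a + b)
    p = pos["position"].to_numpy(dtype=float)
    mirrored = np.where(p <= c, 2.0 * a - p, 2.0 * b - p)
    orig = pos.copy()
    orig["mirrored"] = False
    refl = pos.copy()
    refl["position"] = mirrored
    refl["mirrored"] = True
    out = pd.concat([orig, refl], ignore_index=True)
    out.attrs.update(pos.attrs)
    return out


def profile_grid(a: float, b: float, params: SmoothingParams) -> np.ndarray:
    """Arc-length positions of the trimmed profile subdivisions 1..80."""
    full = mirrored_grid(a, b, params)
    return full[params.trim_lo - 1 : params.trim_hi]


def mirrored_grid(a: float, b: float, params: SmoothingParams) -> np.ndarray:
    """The full ``grid_size`` evaluation grid spanning the mirrored range."""
    c = 0.5 * (a + b)
    return np.linspace(2.0 * a - c, 2.0 * b - c, params.grid_size)


def smooth_profile(
    doubled_pos: np.ndarray,
    values: np.ndarray,
    params: SmoothingParams,
    a: float,
    b: float,
) -> np.ndarray:
    """Loess-smooth one gene over the doubled positions; return 80 values."""
    doubled_pos = np.asarray(doubled_pos, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(doubled_pos) < params.min_points:
        raise ValueError(
            f"need at least {params.min_points} doubled points, got {len(doubled_pos)}"
        )
    if np.ptp(doubled_pos) == 0.0:
        raise ValueError("degenerate positions: all identical")
    grid = mirrored_grid(a, b, params)
    L = loess_matrix(doubled_pos, grid, span=params.span, degree=params.degree)
    full = L @ values
    return full[params.trim_lo - 1 : params.trim_hi]


def build_profile_matrix(
    nm: NormalizedMatrix,
    pos: pd.DataFrame,
    params: SmoothingParams | None = None,
    a: float | None = None,
    b: float | None = None,
) -> pd.DataFrame:
    """Profiles for every gene: rows = genes, columns P1..P80.

    ``pos`` must already be restricted to near-axis nuclei (see
    :func:`select_near_axis`).  The loess smoother depends only on the
    positions, so it is materialized once and applied to all genes by a
    single sparse-dense product; genes with zero expression among the
    selected nuclei get an all-zero profile.
    """
    params = params or SmoothingParams()
    a, b = _termini(pos, a, b)
    bi = nm.barcodes.get_indexer(pos["nucleus_id"])
    if np.any(bi < 0):
        missing = pos["nucleus_id"].to_numpy()[bi < 0][:5]
        raise ValueError(f"position table nuclei missing from matrix: {missing}")
    doubled = mirror_positions(pos, a, b)
    dpos = doubled["position"].to_numpy(dtype=float)
    if len(dpos) < params.min_points:
        raise ValueError(f"too few nuclei for smoothing: {len(pos)}")
    # jitter to break exact position ties (mirror fixed points)
    dpos = dpos + 1e-10 * (b - a) * np.arange(len(dpos))
    grid = mirrored_grid(a, b, params)
    L = loess_matrix(dpos, grid, span=params.span, degree=params.degree)
    Y = nm.values[:, bi]
    Yd = sp.hstack([Y, Y]).tocsr()
    full = np.asarray(Yd @ L.T)
    prof = full[:, params.trim_lo - 1 : params.trim_hi]
    cols = [f"P{i}" for i in range(1, params.n_profile + 1)]
    out = pd.DataFrame(prof, index=nm.genes.copy(), columns=cols)
    out.index.name = "gene_id"
    out.attrs["grid"] = grid[params.trim_lo - 1 : params.trim_hi]
    out.attrs["anterior_terminus"] = a
    out.attrs["posterior_terminus"] = b
    out.attrs["span"] = params.span
    out.attrs["grid_size"] = params.grid_size
    return out
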
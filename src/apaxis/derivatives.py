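"""First-derivative profiles and the correlation statistics built on them.

The first derivative of an expression profile localizes expression-domain
boundaries (its extremes) and peaks (its zeros).  Derivatives use the
central difference at interior subdivisions, d[i] = (x[i+1] - x[i-1]) / 2,
and one-sided differences at the termini, oriented so that positive always
means increasing toward the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import NormalizedMatrix


@dataclass
class Region:
    """A closed interval of subdivision indices (1-based) along the axis."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end <= 80):
            raise ValueError(f"region {self.name}: need 1 <= start < end <= 80")

    @property
    def columns(self) -> list[str]:
        return [f"P{i}" for i in range(self.start, self.end + 1)]


#: the head / thorax / opisthosoma analysis windows
DEFAULT_REGIONS = {
    "A": Region("A", 1, 33),
    "B": Region("B", 28, 58),
    "C": Region("C", 55, 80),
}


def first_derivative(profiles: pd.DataFrame) -> pd.DataFrame:
    """Derivative profile per gene; same shape and labels as the input."""
    vals = profiles.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("profiles contain non-finite values")
    if vals.shape[1] < 3:
        raise ValueError("profiles need at least 3 positions")
    d = np.empty_like(vals)
    d[:, 1:-1] = 0.5 * (vals[:, 2:] - vals[:, :-2])
    d[:, 0] = vals[:, 1] - vals[:, 0]
    d[:, -1] = vals[:, -1] - vals[:, -2]
    return pd.DataFrame(d, index=profiles.index.copy(), columns=profiles.columns.copy())


def top_extremes_table(derivs: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Per position, the k highest and k lowest derivative values.

    Deterministic: ties are broken by gene ID.  Returns a tidy table with
    columns position (1-based), side ('top'/'bottom'), rank, gene_id, value.
    """
    if k > len(derivs):
        raise ValueError(f"k={k} exceeds the gene count ({len(derivs)})")
    rows = []
    genes = derivs.index.to_numpy()
    for j, col in enumerate(derivs.columns, start=1):
        v = derivs[col].to_numpy(dtype=float)
        order = np.lexsort((genes, -v))  # descending value, gene ID tiebreak
        for r, gi in enumerate(order[:k], start=1):
            rows.append((j, "top", r, genes[gi], v[gi]))
        order = np.lexsort((genes, v))
        for r, gi in enumerate(order[:k], start=1):
            rows.append((j, "bottom", r, genes[gi], v[gi]))
    return pd.DataFrame(rows, columns=["position", "side", "rank", "gene_id", "value"])


def position_correlation(
    derivs: pd.DataFrame, genes: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between positions across the gene subset.

    Columns of the derivative matrix are the observations' variables
    (positions), genes the observations.  Zero-variance positions yield
    missing entries rather than spurious values.
    """
    sub = derivs if genes is None else derivs.loc[genes]
    if len(sub) < 3:
        raise ValueError("need at least 3 genes for position correlations")
    corr = sub.corr()  # pandas: pairwise Pearson, NaN on zero variance
    return corr


def region_gene_groups(
    profiles: pd.DataFrame,
    derivs: pd.DataFrame,
    region: Region,
    n_groups: int,
    max_threshold: float = 0.2,
    metric: str = "rows",
) -> pd.Series:
    """Group genes by the similarity of their derivative patterns in a region.

    Genes whose profile maximum inside the region is below ``max_threshold``
    (strictly) are excluded; the gene x gene Pearson map of in-region
    derivatives is computed, and Ward clustering on Euclidean distances
    between its rows (``metric='rows'``) or on sqrt(2(1 - r))
    (``metric='corr_dist'``) is cut into ``n_groups``.
    """
    cols = region.columns
    region_max = profiles[cols].max(axis=1)
    keep = region_max >= max_threshold  # strict "less than" excludes
    d = derivs.loc[keep.index[keep], cols].to_numpy(dtype=float)
    kept_genes = derivs.index[keep]
    var = d.var(axis=1)
    if (var == 0).any():
        kept_genes = kept_genes[var > 0]
        d = d[var > 0]
    if len(kept_genes) < 2:
        raise ValueError(f"fewer than 2 genes survive the region-{region.name} filter")
    if n_groups > len(kept_genes):
        raise ValueError("n_groups exceeds the surviving gene count")
    corr = np.corrcoef(d)
    if metric == "rows":
        dist = pdist(corr)
    elif metric == "corr_dist":
        tri = corr[np.triu_indices_from(corr, k=1)]
        dist = np.sqrt(np.clip(2.0 * (1.0 - tri), 0.0, None))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    labels = fcluster(linkage(dist, method="ward"), t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=kept_genes, name=f"group_{region.name}")


def subdivision_window_to_positions(
    window: tuple[int, int], grid: np.ndarray
) -> tuple[float, float]:
    """Arc-length interval covered by a closed subdivision window."""
    i, j = window
    if not (1 <= i < j <= len(grid)):
        raise ValueError(f"window {window} outside 1..{len(grid)}")
    return float(grid[i - 1]), float(grid[j - 1])


def gene_pair_network(
    nm: NormalizedMatrix,
    pos: pd.DataFrame,
    window: tuple[int, int],
    genes: list[str],
    grid: np.ndarray,
    min_expr_frac: float = 0.10,
    r_threshold: float = 0.5,
) -> pd.DataFrame:
    """Gene-gene co-expression edges over single nuclei in a position window.

    Nuclei whose axis position falls in the closed window are selected (a
    boundary subdivision shared by two windows belongs to both); genes
    expressed in no more than ``min_expr_frac`` of those nuclei are dropped
    (strict "more than"); Pearson correlations over single-nucleus
    expression give edges with r > ``r_threshold`` or r < -``r_threshold``.
    """
    lo, hi = subdivision_window_to_positions(window, grid)
    inside = (pos["position"] >= lo) & (pos["position"] <= hi)
    nuclei = pos.loc[inside, "nucleus_id"]
    if len(nuclei) < 10:
        raise ValueError(f"only {len(nuclei)} nuclei in window {window} (< 10)")
    sub = nm.subset(genes=genes, barcodes=nuclei)
    X = np.asarray(sub.values.todense(), dtype=float)
    frac = (X > 0).mean(axis=1)
    keep = frac > min_expr_frac
    X = X[keep]
    kept_genes = sub.genes[keep]
    edges = []
    if len(kept_genes) >= 2:
        sd = X.std(axis=1)
        ok = sd > 0
        X = X[ok]
        kept_genes = kept_genes[ok]
        if len(kept_genes) >= 2:
            corr = np.corrcoef(X)
            iu, ju = np.triu_indices(len(kept_genes), k=1)
            for i, j in zip(iu, ju):
                r = corr[i, j]
                if r > r_threshold or r < -r_threshold:
                    edges.append(
                        (
                            kept_genes[i],
                            kept_genes[j],
                            float(r),
                            "positive" if r > 0 else "negative",
                            f"{window[0]}-{window[1]}",
                        )
                    )
    return pd.DataFrame(
        edges, columns=["gene_a", "gene_b", "r", "sign", "window"]
    )
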
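"""Perturbation experiments probing where the axial information lives.

Two experiment families: (1) submatrix A/B — re-run clustering and axis
reconstruction with only the selected pattern genes (A) versus everything
except them (B), and score how well each recovers the reference axis; (2)
in-cluster randomization — permute each pattern gene's expression among the
nuclei of one cluster (optionally only a fraction of them, drawn
independently per gene) and measure how locally the embedding degrades.

Because the published readout of these experiments was visual, degradation
is scored explicitly here: ``global_rho`` is the magnitude of the Spearman
correlation between recovered and reference positions (the axis has no
intrinsic orientation in a fresh embedding), and ``continuity`` is the
per-cluster fraction of each nucleus's embedding k-nearest neighbors that
are also among its k nearest neighbors along the reference axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .axis import RidgeError, assign_positions, extract_ridge_control_points, fit_axis_curve, principal_curve
from .clustering import reduce_and_cluster
from .containers import CountMatrix, NormalizedMatrix
from .selection import build_submatrices


@dataclass
class RecoveryScore:
    global_rho: float
    per_cluster_continuity: dict[str, float]
    k: int
    reference: str = "reference"

    @property
    def mean_continuity(self) -> float:
        return float(np.mean(list(self.per_cluster_continuity.values())))


def randomize_cluster_expression(
    nm: NormalizedMatrix | CountMatrix,
    emb: pd.DataFrame,
    cluster: str,
    genes: list[str],
    fraction: float = 1.0,
    seed: int = 0,
):
    """Permute each gene's values among the nuclei of one cluster.

    Each gene gets an independent uniform permutation; with ``fraction`` < 1
    an independent subset of that fraction of the cluster's nuclei is drawn
    per gene and only those values are permuted.  Per-gene within-cluster
    value multisets, everything outside the cluster, and genes outside the
    set are untouched.  Returns a matrix of the same type.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    values = nm.counts if isinstance(nm, CountMatrix) else nm.values
    barcodes = nm.barcodes
    members = emb.loc[emb["cluster"] == cluster, "nucleus_id"]
    cols = barcodes.get_indexer(members)
    cols = cols[cols >= 0]
    if len(cols) < 2:
        raise ValueError(f"cluster {cluster!r} has fewer than 2 nuclei in the matrix")
    gi = nm.genes.get_indexer(genes)
    if np.any(gi < 0):
        missing = [g for g, i in zip(genes, gi) if i < 0]
        raise ValueError(f"genes not in matrix: {missing[:5]}")

    rng = np.random.default_rng(seed)
    block = np.asarray(values[gi][:, cols].todense())
    m = len(cols)
    for r in range(block.shape[0]):
        if fraction < 1.0:
            sub = rng.choice(m, size=max(2, int(round(fraction * m))), replace=False)
        else:
            sub = np.arange(m)
        block[r, sub] = block[r, sub][rng.permutation(len(sub))]
    out = values.tolil(copy=True)
    out[np.ix_(gi, cols)] = block
    out = out.tocsr()
    if isinstance(nm, CountMatrix):
        return CountMatrix(nm.genes, nm.barcodes, out)
    return NormalizedMatrix(nm.genes, nm.barcodes, out, nm.scale_factor)


def _embedding_positions(emb: pd.DataFrame, axis_clusters=None) -> pd.DataFrame:
    """1-D positions for an embedding: full axis pipeline, principal-curve
    fallback when no elongated ridge exists (e.g. a collapsed embedding)."""
    clusters = set(emb["cluster"]) if axis_clusters is None else set(axis_clusters)
    try:
        control, anchors = extract_ridge_control_points(emb, clusters)
        curve = fit_axis_curve(control, anchors, n_polyline=2000)
        return assign_positions(emb, curve, clusters, keep_omitted=True)
    except (RidgeError, ValueError):
        sel = emb[emb["cluster"].isin(clusters)]
        _, t = principal_curve(sel[["x", "y"]].to_numpy(dtype=float))
        return pd.DataFrame({"nucleus_id": sel["nucleus_id"].to_numpy(), "position": t})


def _knn_indices_2d(coords: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    return idx[:, 1:]


def _knn_indices_1d(x: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(x))
    n = len(x)
    out = np.empty((n, k), dtype=np.int64)
    xs = x[order]
    for i in range(n):
        r = rank[i]
        lo = max(0, r - k)
        hi = min(n, r + k + 1)
        cand = np.arange(lo, hi)
        cand = cand[cand != r]
        d = np.abs(xs[cand] - x[i])
        pick = cand[np.argsort(d, kind="stable")[:k]]
        out[i] = order[pick]
    return out


def axis_recovery_score(
    recovered: pd.DataFrame,
    reference: pd.DataFrame,
    k: int = 30,
    cluster_labels: pd.Series | None = None,
) -> RecoveryScore:
    """Score recovered positions (or a 2-D embedding) against a reference.

    ``recovered``: a position table (nucleus_id, position) or an embedding
    (nucleus_id, x, y[, cluster]).  ``reference``: nucleus_id plus a ``u`` or
    ``position`` column.  ``cluster_labels`` (nucleus_id-indexed) overrides
    the grouping used for per-cluster continuity, so continuity can be
    reported against the unperturbed clustering.
    """
    ref_col = "u" if "u" in reference.columns else "position"
    ref = (
        reference[["nucleus_id", ref_col]]
        .dropna()
        .rename(columns={ref_col: "reference_position"})
    )
    is_embedding = {"x", "y"}.issubset(recovered.columns)
    if is_embedding:
        pos_tab = _embedding_positions(recovered)
    else:
        pos_tab = recovered[["nucleus_id", "position"]]
    merged = pos_tab.merge(ref, on="nucleus_id")
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} shared nuclei (< 10)")
    rho = abs(
        float(spearmanr(merged["position"], merged["reference_position"]).statistic)
    )

    # continuity on the recovered geometry
    if is_embedding:
        coords = (
            recovered.set_index("nucleus_id")
            .loc[merged["nucleus_id"], ["x", "y"]]
            .to_numpy(dtype=float)
        )
        nn = _knn_indices_2d(coords, k)
    else:
        nn = _knn_indices_1d(merged["position"].to_numpy(dtype=float), k)
    ref_nn = _knn_indices_1d(merged["reference_position"].to_numpy(dtype=float), k)
    overlap = np.fromiter(
        (
            len(set(nn[i]).intersection(ref_nn[i])) / k
            for i in range(len(merged))
        ),
        dtype=float,
    )
    if cluster_labels is not None:
        labels = cluster_labels.reindex(merged["nucleus_id"]).to_numpy()
    elif is_embedding and "cluster" in recovered.columns:
        labels = (
            recovered.set_index("nucleus_id")
            .loc[merged["nucleus_id"], "cluster"]
            .to_numpy()
        )
    else:
        labels = np.full(len(merged), "all")
    cont = {
        str(cl): float(overlap[labels == cl].mean()) for cl in pd.unique(labels)
    }
    return RecoveryScore(global_rho=rho, per_cluster_continuity=cont, k=k)


DEFAULT_EMBED_CONFIG = dict(
    n_variable=2000, n_dims=50, resolution=1.0, seed=0, embedding="umap"
)


def _embed(nm: NormalizedMatrix, config: dict) -> pd.DataFrame:
    cfg = {**DEFAULT_EMBED_CONFIG, **(config or {})}
    cfg["n_dims"] = min(cfg["n_dims"], min(nm.shape) - 1)
    return reduce_and_cluster(nm, **cfg)


def run_submatrix_experiment(
    nm: NormalizedMatrix,
    selected_genes,
    axis_barcodes,
    reference: pd.DataFrame,
    config: dict | None = None,
    k: int = 30,
) -> tuple[RecoveryScore, RecoveryScore]:
    """Re-embed submatrices A (selected genes) and B (complement) and score
    axis recovery of each against the reference positions."""
    sub_a, sub_b = build_submatrices(nm, axis_barcodes, selected_genes)
    scores = []
    for sub in (sub_a, sub_b):
        emb = _embed(sub, config)
        scores.append(axis_recovery_score(emb, reference, k=k))
    return scores[0], scores[1]


def run_randomization_sweep(
    nm: NormalizedMatrix,
    emb: pd.DataFrame,
    cluster: str,
    genes: list[str],
    fractions: list[float],
    seeds: list[int],
    reference: pd.DataFrame,
    config: dict | None = None,
    k: int = 30,
) -> pd.DataFrame:
    """Perturb, re-embed, and score for every (fraction, seed) pair.

    Re-embedding uses the fixed seed in ``config`` for every run, shared
    with the unperturbed baseline, so score differences reflect the
    perturbation rather than embedding stochasticity.  Returns a tidy table:
    fraction, seed, global_rho, target_continuity, other_continuity.
    """
    cluster_labels = emb.set_index("nucleus_id")["cluster"]
    rows = []
    for seed in seeds:
        for frac in fractions:
            pert_seed = int(np.random.default_rng([seed, int(round(1000 * frac))]).integers(2**31))
            pert = randomize_cluster_expression(
                nm, emb, cluster, genes, fraction=frac, seed=pert_seed
            )
            emb2 = _embed(pert, config)
            score = axis_recovery_score(
                emb2, reference, k=k, cluster_labels=cluster_labels
            )
            cont = score.per_cluster_continuity
            target = cont.get(str(cluster), np.nan)
            others = [v for c, v in cont.items() if c != str(cluster)]
            rows.append(
                (
                    frac,
                    seed,
                    score.global_rho,
                    target,
                    float(np.mean(others)) if others else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["fraction", "seed", "global_rho", "target_continuity", "other_continuity"],
    )
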
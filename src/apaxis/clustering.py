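"""Variable features, PCA, graph clustering, 2-D embedding, and markers.

These are the standard single-cell stages, delegated to scanpy (Leiden
partitioning via igraph/leidenalg, UMAP via umap-learn) and parameterized as
used for the germ-band nucleus data: 2000 variable features, 50 principal
components, shared-nearest-neighbor graph, modularity clustering at a chosen
resolution.  Only the parameterization and contracts live here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix


def _scanpy():
    import scanpy as sc

    sc.settings.verbosity = 0
    return sc


def reduce_and_cluster(
    nm: NormalizedMatrix,
    n_variable: int = 2000,
    n_dims: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    embedding: str = "umap",
) -> pd.DataFrame:
    """Cluster and embed: variable features -> scale -> PCA -> SNN graph ->
    Leiden -> 2-D embedding.  Deterministic given ``seed``.

    ``embedding='pca'`` uses the first two principal components as the 2-D
    coordinates — a fast, deterministic stand-in useful in large perturbation
    sweeps.  Returns an EmbeddingTable: nucleus_id, x, y, cluster.
    """
    sc = _scanpy()
    n_genes, n_nuclei = nm.shape
    if n_dims >= min(n_genes, n_nuclei):
        raise ValueError(
            f"n_dims={n_dims} must be < min(genes, nuclei) = {min(n_genes, n_nuclei)}"
        )
    adata = nm.to_anndata()
    n_variable = min(n_variable, n_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_variable, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
        sc.pp.scale(adata, max_value=10)
        sc.tl.pca(adata, n_comps=min(n_dims, adata.n_vars - 1), svd_solver="arpack")
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
        if embedding == "umap":
            sc.tl.umap(adata, random_state=seed)
            coords = adata.obsm["X_umap"]
        elif embedding == "pca":
            coords = adata.obsm["X_pca"][:, :2]
        else:
            raise ValueError(f"unknown embedding {embedding!r}")
    emb = pd.DataFrame(
        {
            "nucleus_id": nm.barcodes.to_numpy(),
            "x": np.asarray(coords[:, 0], dtype=float),
            "y": np.asarray(coords[:, 1], dtype=float),
            "cluster": adata.obs["leiden"].astype(str).to_numpy(),
        }
    )
    if not np.isfinite(emb[["x", "y"]].to_numpy()).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    emb.attrs["resolution"] = resolution
    emb.attrs["dims"] = n_dims
    emb.attrs["seed"] = seed
    return emb


def find_cluster_markers(
    nm: NormalizedMatrix,
    emb: pd.DataFrame,
    min_pct_in: float = 0.25,
    max_pct_out: float = 0.90,
    alpha: float = 1e-3,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers per cluster with percent-expressed filters.

    A gene is a marker of a cluster when it is expressed in more than
    ``min_pct_in`` of that cluster's nuclei, in less than ``max_pct_out`` of
    the other nuclei, and its adjusted p-value is below ``alpha`` (all
    strict).  Clusters with fewer than 3 nuclei are skipped with a warning.
    """
    sc = _scanpy()
    clusters = emb.set_index("nucleus_id")["cluster"]
    if clusters.nunique() < 2:
        raise ValueError("need at least 2 clusters for marker identification")
    adata = nm.to_anndata()
    adata.obs["cluster"] = pd.Categorical(clusters.reindex(adata.obs_names))
    sizes = adata.obs["cluster"].value_counts()
    small = sizes[sizes < 3].index.tolist()
    if small:
        warnings.warn(
            f"skipping clusters with < 3 nuclei: {small}", RuntimeWarning, stacklevel=2
        )
    groups = [c for c in sizes.index if sizes[c] >= 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            adata,
            "cluster",
            groups=groups,
            method="wilcoxon",
            corr_method="bonferroni" if correction == "bonferroni" else "benjamini-hochberg",
            pts=True,
        )
    res = adata.uns["rank_genes_groups"]
    pts = res["pts"]
    pts_rest = res["pts_rest"]
    frames = []
    for grp in groups:
        df = pd.DataFrame(
            {
                "gene_id": res["names"][grp],
                "cluster": grp,
                "adjusted_p": res["pvals_adj"][grp],
                "effect": res["logfoldchanges"][grp],
            }
        )
        df["pct_in"] = pts.loc[df["gene_id"], grp].to_numpy()
        df["pct_out"] = pts_rest.loc[df["gene_id"], grp].to_numpy()
        frames.append(df)
    allm = pd.concat(frames, ignore_index=True)
    markers = allm[
        (allm["pct_in"] > min_pct_in)
        & (allm["pct_out"] < max_pct_out)
        & (allm["adjusted_p"] < alpha)
    ].reset_index(drop=True)
    return markers[["gene_id", "cluster", "pct_in", "pct_out", "adjusted_p", "effect"]]


def diagnose_low_quality_clusters(
    cm: CountMatrix, emb: pd.DataFrame, fraction: float = 0.7
) -> pd.DataFrame:
    """Flag clusters whose median gene and molecule counts are both low.

    A cluster is flagged when both its median detected-gene count and its
    median molecule count fall below ``fraction`` of the global medians —
    the signature of a pseudocluster driven by data quality rather than a
    cell state.  Flags are advisory.
    """
    n_genes = pd.Series(cm.genes_detected(), index=cm.barcodes)
    n_mol = pd.Series(cm.molecules(), index=cm.barcodes)
    global_g = float(n_genes.median())
    global_m = float(n_mol.median())
    rows = []
    for cl, grp in emb.groupby("cluster"):
        ids = grp["nucleus_id"]
        mg = float(n_genes.reindex(ids).median())
        mm = float(n_mol.reindex(ids).median())
        rows.append(
            (
                cl,
                len(ids),
                mg,
                mm,
                bool(mg < fraction * global_g and mm < fraction * global_m),
            )
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n_nuclei", "median_genes", "median_molecules", "flagged"]
    )


def subsample_nuclei(
    cm: CountMatrix, n: int, trials: int, seed: int
) -> list[CountMatrix]:
    """``trials`` uniform without-replacement subsamples of ``n`` nuclei.

    Per-trial seeds are derived deterministically from the master seed, so
    the whole family of subsamples is reproducible.
    """
    if n > cm.shape[1]:
        raise ValueError(f"cannot sample {n} of {cm.shape[1]} nuclei")
    master = np.random.default_rng(seed)
    out = []
    for _ in range(trials):
        child = np.random.default_rng(int(master.integers(2**31)))
        cols = child.choice(cm.shape[1], size=n, replace=False)
        out.append(CountMatrix(cm.genes, cm.barcodes[cols], cm.counts[:, cols]))
    return out
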
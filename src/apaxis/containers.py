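"""In-memory containers for gene x nucleus matrices.

Matrices are stored gene-major (rows = genes, columns = nuclei), mirroring the
10x/MatrixMarket triplet layout in which features index the rows.  Conversion
to :class:`anndata.AnnData` (nuclei-major, the scanpy convention) is provided
for the delegated clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _check_ids(ids: pd.Index, what: str) -> pd.Index:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x nuclei."""

    genes: pd.Index
    barcodes: pd.Index
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = _check_ids(self.genes, "gene IDs")
        self.barcodes = _check_ids(self.barcodes, "barcodes")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise ValueError("negative counts present")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts present")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.counts.eliminate_zeros()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per nucleus."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def molecules(self) -> np.ndarray:
        """Total molecules (UMI counts) per nucleus."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_barcodes(self, keep: np.ndarray | list) -> "CountMatrix":
        idx = self.barcodes.get_indexer(keep) if not np.issubdtype(
            np.asarray(keep).dtype, np.integer
        ) else np.asarray(keep)
        if np.any(idx < 0):
            raise KeyError("unknown barcodes in subset")
        return CountMatrix(self.genes, self.barcodes[idx], self.counts[:, idx])

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(X=self.counts.T.astype(np.float32).tocsr())
        adata.obs_names = self.barcodes.astype(str)
        adata.var_names = self.genes.astype(str)
        return adata


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x nuclei; zero count <-> zero value."""

    genes: pd.Index
    barcodes: pd.Index
    values: sp.csr_matrix
    scale_factor: float = field(default=1.0e4)

    def __post_init__(self) -> None:
        self.genes = _check_ids(self.genes, "gene IDs")
        self.barcodes = _check_ids(self.barcodes, "barcodes")
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr().astype(np.float64)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("values shape does not match gene/barcode tables")
        if self.values.data.size and (self.values.data < 0).any():
            raise ValueError("negative normalized values present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, genes=None, barcodes=None) -> "NormalizedMatrix":
        v = self.values
        g, b = self.genes, self.barcodes
        if genes is not None:
            gi = self.genes.get_indexer(genes)
            if np.any(gi < 0):
                raise KeyError("unknown genes in subset")
            v = v[gi]
            g = self.genes[gi]
        if barcodes is not None:
            bi = self.barcodes.get_indexer(barcodes)
            if np.any(bi < 0):
                raise KeyError("unknown barcodes in subset")
            v = v[:, bi]
            b = self.barcodes[bi]
        return NormalizedMatrix(g, b, v, self.scale_factor)

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(X=self.values.T.astype(np.float32).tocsr())
        adata.obs_names = self.barcodes.astype(str)
        adata.var_names = self.genes.astype(str)
        return adata
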
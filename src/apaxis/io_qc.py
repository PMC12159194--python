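"""Count-matrix IO, nucleus QC filtering, and log-normalization.

QC keeps nuclei with *more than* ``min_genes`` detected genes and *fewer
than* ``max_molecules`` total molecules — both strict inequalities, the
convention used when filtering doublets and low-quality nuclei from
droplet/well-based single-nucleus data.  Presets for the three library types
analysed with this pipeline are in :data:`QC_PRESETS`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountMatrix, NormalizedMatrix

#: (min_genes, max_molecules) per library type
QC_PRESETS: dict[str, tuple[int, int]] = {
    "stage7_cell": (1500, 20000),
    "stage7_nucleus": (2000, 20000),
    "latestage5_nucleus": (1500, 15000),
}

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


def read_count_matrix(path: str | Path, dialect: str = "mtx_triplet") -> CountMatrix:
    """Read a gene x nucleus count matrix.

    ``mtx_triplet``: a directory holding ``matrix.mtx`` (genes as rows) plus
    ``features.tsv`` and ``barcodes.tsv`` (one ID per line).  ``dense_csv``:
    a single CSV with gene IDs in the first column and barcodes as header.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mtx = path / MTX_NAME
        feats = path / FEATURES_NAME
        bcs = path / BARCODES_NAME
        for p in (mtx, feats, bcs):
            if not p.exists():
                raise FileNotFoundError(f"missing input file: {p}")
        try:
            counts = mmread(mtx)
        except Exception as exc:  # malformed triplet: report the location
            raise ValueError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        genes = pd.read_csv(feats, sep="\t", header=None)[0]
        barcodes = pd.read_csv(bcs, sep="\t", header=None)[0]
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"{mtx}: matrix is {counts.shape} but ID tables give "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        try:
            return CountMatrix(pd.Index(genes), pd.Index(barcodes), counts)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    if dialect == "dense_csv":
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        df = pd.read_csv(path, index_col=0)
        try:
            return CountMatrix(
                pd.Index(df.index), pd.Index(df.columns), sp.csr_matrix(df.to_numpy())
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> None:
    """Write the MatrixMarket triplet layout; round-trips bit-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / MTX_NAME, cm.counts.tocoo(), field="integer")
    pd.Series(cm.genes).to_csv(outdir / FEATURES_NAME, sep="\t", index=False, header=False)
    pd.Series(cm.barcodes).to_csv(outdir / BARCODES_NAME, sep="\t", index=False, header=False)


def qc_filter(
    cm: CountMatrix, min_genes: int, max_molecules: int
) -> tuple[CountMatrix, pd.DataFrame]:
    """Strictly filter nuclei: genes detected > min_genes AND molecules < max.

    Returns the retained matrix and a removal report listing each removed
    barcode with the criterion it failed.
    """
    if min_genes <= 0 or max_molecules <= 0:
        raise ValueError("QC thresholds must be positive")
    if cm.shape[1] == 0:
        raise ValueError("empty matrix: no nuclei to filter")
    n_genes = cm.genes_detected()
    n_mol = cm.molecules()
    keep = (n_genes > min_genes) & (n_mol < max_molecules)
    reasons = []
    for i in np.flatnonzero(~keep):
        why = []
        if n_genes[i] <= min_genes:
            why.append("low_genes")
        if n_mol[i] >= max_molecules:
            why.append("high_molecules")
        reasons.append(
            (cm.barcodes[i], int(n_genes[i]), int(n_mol[i]), "+".join(why))
        )
    report = pd.DataFrame(
        reasons, columns=["barcode", "n_genes", "n_molecules", "failed"]
    )
    kept = CountMatrix(cm.genes, cm.barcodes[keep], cm.counts[:, np.flatnonzero(keep)])
    return kept, report


def log_normalize(cm: CountMatrix, scale_factor: float = 1.0e4) -> NormalizedMatrix:
    """value = ln(1 + count * scale_factor / column_total), sparsity preserved."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.molecules().astype(float)
    if (totals == 0).any():
        bad = cm.barcodes[totals == 0].tolist()[:5]
        raise ValueError(f"zero-total nuclei present (QC should remove them): {bad}")
    csc = cm.counts.tocsc().astype(np.float64)
    # scale each column by scale_factor / total, then log1p the stored entries
    scaled = csc @ sp.diags(1.0 / totals) * scale_factor
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(cm.genes, cm.barcodes, scaled.tocsr(), scale_factor)
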
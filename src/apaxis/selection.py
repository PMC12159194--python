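"""Pattern-gene selection from expression profiles.

Two stages mirror the analysis workflow: (1) genes detected only in a
handful of scattered nuclei are excluded by clustering the per-gene minimum
inter-expressing-nucleus distance along the axis into two Ward groups and
dropping the large-gap group; (2) the remaining genes are clustered twice on
the (mean, max - min) features of their 80-position profiles, and groups
whose centroids combine relatively low mean expression with a large
expression range — the signature of a localized or striped gene — are
selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .containers import NormalizedMatrix


def min_expression_gaps(nm: NormalizedMatrix, pos: pd.DataFrame) -> pd.Series:
    """Per gene, the minimum |position difference| between expressing nuclei.

    Sentinel: genes with fewer than 2 expressing nuclei get the full axis
    length (they are maximally sparse by convention).
    """
    bi = nm.barcodes.get_indexer(pos["nucleus_id"])
    ok = bi >= 0
    if not ok.any():
        raise ValueError("no positioned nuclei found in the matrix")
    bi = bi[ok]
    p = pos["position"].to_numpy(dtype=float)[ok]
    a = pos.attrs.get("anterior_terminus", float(p.min()))
    b = pos.attrs.get("posterior_terminus", float(p.max()))
    axis_len = float(b - a)
    csc = nm.values[:, bi].tocsr()
    gaps = np.full(len(nm.genes), axis_len)
    indptr, indices = csc.indptr, csc.indices
    for g in range(len(nm.genes)):
        cols = indices[indptr[g] : indptr[g + 1]]
        if cols.size < 2:
            continue
        pg = np.sort(p[cols])
        gaps[g] = float(np.min(np.diff(pg)))
    out = pd.Series(gaps, index=nm.genes.copy(), name="min_expr_gap")
    out.attrs["axis_length"] = axis_len
    return out


def sparse_gene_filter(
    nm: NormalizedMatrix, pos: pd.DataFrame
) -> tuple[pd.Index, pd.Index, pd.Series]:
    """Split genes into retained (dense) and excluded (sparse) sets.

    Ward clustering (the ward.D2 criterion on Euclidean distances) of the
    scalar minimum-gap feature into two groups; the group with the larger
    mean gap is the sparse one.
    """
    gaps = min_expression_gaps(nm, pos)
    vals = gaps.to_numpy().reshape(-1, 1)
    if np.ptp(vals) == 0.0:
        raise ValueError("all genes equally sparse: cannot split into two groups")
    lab = fcluster(linkage(vals, method="ward"), t=2, criterion="maxclust")
    means = [vals[lab == k].mean() for k in (1, 2)]
    sparse_label = 1 + int(np.argmax(means))
    excluded = gaps.index[lab == sparse_label]
    retained = gaps.index[lab != sparse_label]
    if len(retained) == 0:
        raise ValueError("all genes classified sparse; check positions/expression")
    return retained, excluded, gaps


def compute_pattern_features(profiles: pd.DataFrame) -> pd.DataFrame:
    """(mean, max - min) of each gene's 80-position profile."""
    vals = profiles.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "mean": vals.mean(axis=1),
            "diff": vals.max(axis=1) - vals.min(axis=1),
        },
        index=profiles.index.copy(),
    )


def _passes_rule(
    centroid_mean: float, centroid_diff: float, med_mean: float, diff_thr: float
) -> bool:
    return centroid_diff > diff_thr and centroid_mean < med_mean


def two_round_select(
    features: pd.DataFrame,
    k1: int = 12,
    k2_range: tuple[int, int] = (2, 5),
    rule: str = "median",
    whitelist: set[str] | None = None,
    standardize: bool = True,
    diff_margin: float = 2.0,
) -> pd.DataFrame:
    """Two rounds of Ward clustering on (mean, diff); select striped groups.

    Round 1 cuts the tree into ``k1`` groups; a group is kept when its
    centroid combines a relatively small mean with a relatively large
    expression range (``rule='median'``): mean below the grand median of
    means, and diff above the grand median of diffs by at least
    ``diff_margin`` robust units (median absolute deviations).  The margin
    codifies "relatively large": a group drawn from the unpatterned bulk
    has a centroid diff pinned near the grand median and never clears it,
    while genuinely striped genes exceed it many times over.  With
    ``rule='whitelist'`` group IDs are chosen explicitly (replicating a
    manual choice; round-2 subgroups are addressed ``"<g>.<s>"``).  Each
    kept group is re-clustered into k in ``k2_range`` subgroups (k by
    maximum silhouette, ties to the smaller k) and subgroups are filtered
    by the same rule.  Returns one row per gene: round1_group,
    round2_group, selected.
    """
    if k1 < 2:
        raise ValueError("k1 must be >= 2")
    if k1 > len(features):
        raise ValueError(f"k1={k1} exceeds the number of genes ({len(features)})")
    if rule not in ("median", "whitelist"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "whitelist":
        whitelist = set() if whitelist is None else {str(w) for w in whitelist}

    X = features[["mean", "diff"]].to_numpy(dtype=float)
    med_mean, med_diff = np.median(X[:, 0]), np.median(X[:, 1])
    mad_diff = np.median(np.abs(X[:, 1] - med_diff))
    diff_thr = med_diff + diff_margin * mad_diff
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X

    r1 = fcluster(linkage(Z, method="ward"), t=k1, criterion="maxclust")
    result = pd.DataFrame(
        {
            "round1_group": r1,
            "round2_group": 0,
            "selected": False,
        },
        index=features.index.copy(),
    )

    def kept1(g: int) -> bool:
        if rule == "whitelist":
            return str(g) in whitelist or any(
                w.startswith(f"{g}.") for w in whitelist
            )
        m = r1 == g
        return _passes_rule(X[m, 0].mean(), X[m, 1].mean(), med_mean, diff_thr)

    lo, hi = k2_range
    for g in np.unique(r1):
        mask = r1 == g
        size = int(mask.sum())
        # round 2 runs for every group (subgrouping is informative even for
        # unselected groups); only kept round-1 groups contribute selections
        if size <= 2:
            sub = np.ones(size, dtype=int)
        else:
            best_k, best_s = None, -np.inf
            for k in range(lo, min(hi, size - 1) + 1):
                labs = fcluster(linkage(Z[mask], method="ward"), t=k, criterion="maxclust")
                if len(np.unique(labs)) < 2:
                    continue
                s = silhouette_score(Z[mask], labs)
                if s > best_s + 1e-12:
                    best_k, best_s = k, s
            if best_k is None:
                sub = np.ones(size, dtype=int)
            else:
                sub = fcluster(
                    linkage(Z[mask], method="ward"), t=best_k, criterion="maxclust"
                )
        result.loc[mask, "round2_group"] = sub
        if not kept1(g):
            continue
        Xg = X[mask]
        for s in np.unique(sub):
            sm = sub == s
            if rule == "whitelist":
                keep = f"{g}.{s}" in whitelist or str(g) in whitelist
            else:
                keep = _passes_rule(
                    Xg[sm, 0].mean(), Xg[sm, 1].mean(), med_mean, diff_thr
                )
            if keep:
                idx = result.index[mask][sm]
                result.loc[idx, "selected"] = True
    return result


def build_submatrices(
    nm: NormalizedMatrix,
    axis_barcodes,
    selected_genes,
) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Submatrix A (selected genes x axis nuclei) and B (the complement).

    A and B partition the gene universe over an identical, identically
    ordered nucleus set — the substrate of the "where does the axial
    information live" experiment.
    """
    selected = pd.Index(selected_genes)
    if len(selected) == 0:
        raise ValueError("selected gene set is empty")
    missing = selected.difference(nm.genes)
    if len(missing):
        raise ValueError(f"selected genes not in matrix: {missing.tolist()[:5]}")
    complement = nm.genes.difference(selected, sort=False)
    if len(complement) == 0:
        raise ValueError("selected set covers every gene; submatrix B would be empty")
    sub_a = nm.subset(genes=selected, barcodes=axis_barcodes)
    sub_b = nm.subset(genes=complement, barcodes=axis_barcodes)
    return sub_a, sub_b
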
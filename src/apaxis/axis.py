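"""Reconstruction of the anterior-posterior axis from a 2-D embedding.

The elongated ectoderm supercluster in a single-nucleus embedding traces the
embryo's AP axis.  This module recovers that axis as a curve: control points
are placed on the density ridge of the axis clusters (automatically via a
principal-curve tracer, or supplied manually), oriented from an anterior to a
posterior anchor defined by terminal marker genes, joined by an interpolating
cubic spline, extended past both termini, discretized into evenly spaced
polyline points with cumulative arc-length positions, and finally each
nucleus is assigned the position of (and distance to) its nearest polyline
point.  Nuclei whose nearest point falls on an extension segment lie beyond
the termini and are omitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .containers import NormalizedMatrix
from .smoothing import loess_fit


class RidgeError(RuntimeError):
    """Automatic ridge tracing failed (no elongated component)."""


@dataclass
class AxisCurve:
    control_points: np.ndarray  # (m, 2), anterior-first
    anterior_anchor: np.ndarray
    posterior_anchor: np.ndarray
    extension_points: np.ndarray  # (2, 2): anterior, posterior extension tips
    polyline: np.ndarray  # (N, 2) evenly spaced by arc length
    positions: np.ndarray  # (N,) cumulative arc length from the anterior end
    on_extension: np.ndarray  # (N,) bool
    anterior_terminus: float  # arc-length position of the anterior anchor
    posterior_terminus: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("arc-length positions must be strictly increasing")
        if not self.anterior_terminus < self.posterior_terminus:
            raise ValueError("anterior terminus must precede posterior terminus")

    @property
    def axis_length(self) -> float:
        return self.posterior_terminus - self.anterior_terminus

    def to_json_dict(self, thin: int = 100) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "anterior_anchor": self.anterior_anchor.tolist(),
            "posterior_anchor": self.posterior_anchor.tolist(),
            "extension_points": self.extension_points.tolist(),
            "anterior_terminus": self.anterior_terminus,
            "posterior_terminus": self.posterior_terminus,
            "polyline_thinned": self.polyline[::thin].tolist(),
        }


def _polyline_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def principal_curve(
    pts: np.ndarray,
    span: float = 0.35,
    n_iter: int = 8,
    n_grid: int = 200,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a smooth 1-D curve through a 2-D point cloud.

    Iterates the classic projection/smoothing scheme: initialize the latent
    parameter from the first principal axis, smooth each coordinate against
    the parameter with loess, reproject points onto the smoothed curve, and
    re-parametrize by arc length.  Returns (curve, t): the curve as an
    (n_grid, 2) polyline and each point's arc-length parameter on it.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 10:
        raise ValueError("need an (n, 2) array with n >= 10")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]

    curve = None
    for _ in range(n_iter):
        # jitter breaks exact parameter ties that destabilize the local fits
        tj = t + 1e-9 * np.ptp(t) * np.arange(len(t))
        grid = np.linspace(tj.min(), tj.max(), n_grid)
        cx = loess_fit(tj, pts[:, 0], grid, span=span, degree=degree)
        cy = loess_fit(tj, pts[:, 1], grid, span=span, degree=degree)
        curve = np.column_stack([cx, cy])
        arc = _polyline_arclength(curve)
        # densify for projection
        dense_arc = np.linspace(0.0, arc[-1], 10 * n_grid)
        dense = np.column_stack(
            [np.interp(dense_arc, arc, curve[:, 0]), np.interp(dense_arc, arc, curve[:, 1])]
        )
        _, idx = cKDTree(dense).query(pts)
        t_new = dense_arc[idx]
        if np.allclose(np.sort(t_new), np.sort(t), atol=1e-6 * max(arc[-1], 1.0)):
            t = t_new
            break
        t = t_new
    return curve, t


def _density_peak(pts: np.ndarray) -> np.ndarray:
    """Location of the highest kernel density estimate among the points."""
    if len(pts) < 5:
        raise ValueError("too few points for a density peak")
    kde = gaussian_kde(pts.T)  # Scott's rule bandwidth
    dens = kde(pts.T)
    return pts[np.argmax(dens)]


def _ridge_refine(
    control: np.ndarray, pts: np.ndarray, n_pass: int = 2
) -> np.ndarray:
    """Shift control points along their local normals toward density maxima.

    One mean-shift step per pass, restricted to the normal direction so the
    along-curve spacing of the control points is preserved.
    """
    n = len(pts)
    # Scott's rule bandwidth per dimension, averaged
    h = float(np.mean(pts.std(axis=0, ddof=1))) * n ** (-1.0 / 6.0)
    h = max(h, 1e-9)
    out = control.copy()
    for _ in range(n_pass):
        for i in range(len(out)):
            lo, hi = max(0, i - 1), min(len(out) - 1, i + 1)
            tangent = out[hi] - out[lo]
            norm = np.linalg.norm(tangent)
            if norm == 0:
                continue
            tangent /= norm
            normal = np.array([-tangent[1], tangent[0]])
            d2 = ((pts - out[i]) ** 2).sum(axis=1)
            w = np.exp(-0.5 * d2 / (2.0 * h) ** 2)
            if w.sum() <= 0:
                continue
            shift = float(np.dot(w, (pts - out[i]) @ normal) / w.sum())
            out[i] = out[i] + shift * normal
    return out


def extract_ridge_control_points(
    emb: pd.DataFrame,
    axis_clusters: set[str] | list[str],
    anchor_genes: tuple[list[str], list[str]] | None = None,
    nm: NormalizedMatrix | None = None,
    manual_points: np.ndarray | None = None,
    n_control: int = 12,
    span: float = 0.35,
    min_elongation: float = 2.0,
    max_wiggle: float = 1.8,
    density_refine: bool = True,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Control points along the density ridge of the axis clusters.

    With ``manual_points`` the supplied points are used verbatim (the
    replication mode in which a human places points on the density-contour
    ridge); otherwise a principal curve is traced through the axis-cluster
    nuclei and sampled at ``n_control`` evenly spaced arc positions, each
    nudged onto the local density maximum.  When ``anchor_genes`` =
    (anterior set, posterior set) and ``nm`` are given, the anchors are the
    density peaks of the nuclei expressing each set and the curve is oriented
    and trimmed anterior -> posterior; otherwise the anchors are the traced
    curve's endpoints and orientation is arbitrary.
    """
    if manual_points is not None:
        manual_points = np.asarray(manual_points, dtype=float)
        if len(manual_points) < 2:
            raise ValueError("need at least 2 manual points")
        return manual_points.copy(), (manual_points[0].copy(), manual_points[-1].copy())

    axis_clusters = set(axis_clusters)
    if not axis_clusters:
        raise ValueError("axis_clusters must be non-empty")
    sel = emb[emb["cluster"].isin(axis_clusters)]
    if len(sel) < 10:
        raise ValueError("too few nuclei in axis clusters")
    pts = sel[["x", "y"]].to_numpy(dtype=float)

    curve, t = principal_curve(pts, span=span)
    arc = _polyline_arclength(curve)
    length = arc[-1]
    # "no elongated component" diagnostics.  An isotropic cloud defeats the
    # tracer in one of two ways: the curve folds repeatedly through the cloud
    # (length far exceeding the cloud diameter), or it stays short relative
    # to the transverse spread of the points around it.
    diag = float(np.hypot(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
    wiggle = length / max(diag, 1e-12)
    _, idx = cKDTree(curve).query(pts)
    perp = np.linalg.norm(pts - curve[idx], axis=1)
    elong = length / max(4.0 * np.median(perp), 1e-12)
    if wiggle > max_wiggle:
        raise RidgeError(
            f"no elongated component: traced curve folds through the cloud "
            f"(length {length:.3g} vs cloud diameter {diag:.3g}, "
            f"ratio {wiggle:.2f} > {max_wiggle})"
        )
    if elong < min_elongation:
        raise RidgeError(
            f"no elongated component: curve length {length:.3g} vs transverse "
            f"spread {np.median(perp):.3g} (elongation {elong:.2f} < {min_elongation})"
        )

    targets = np.linspace(0.0, length, n_control)
    control = np.column_stack(
        [np.interp(targets, arc, curve[:, 0]), np.interp(targets, arc, curve[:, 1])]
    )
    if density_refine:
        control = _ridge_refine(control, pts)

    if anchor_genes is None or nm is None:
        return control, (control[0].copy(), control[-1].copy())

    ant_genes, post_genes = anchor_genes
    anchors = []
    for gene_set, side in ((ant_genes, "anterior"), (post_genes, "posterior")):
        gi = nm.genes.get_indexer(gene_set)
        if np.any(gi < 0):
            missing = [g for g, i in zip(gene_set, gi) if i < 0]
            raise ValueError(f"{side} anchor genes not in matrix: {missing}")
        bi = nm.barcodes.get_indexer(sel["nucleus_id"])
        if np.any(bi < 0):
            raise ValueError("embedding nuclei missing from expression matrix")
        expr = np.asarray(nm.values[gi][:, bi].sum(axis=0)).ravel()
        expressing = expr > 0
        if expressing.sum() < 5:
            raise ValueError(
                f"{side} anchor ill-defined: genes expressed in "
                f"{int(expressing.sum())} nuclei (< 5)"
            )
        anchors.append(_density_peak(pts[expressing]))
    ant, post = anchors

    # orient anterior -> posterior using the anchors' projections on the curve
    ctrl_arc = _polyline_arclength(control)
    proj = cKDTree(control).query(np.vstack([ant, post]))[1]
    t_ant, t_post = ctrl_arc[proj[0]], ctrl_arc[proj[1]]
    if t_ant > t_post:
        control = control[::-1].copy()
        ctrl_arc = _polyline_arclength(control)
        proj = cKDTree(control).query(np.vstack([ant, post]))[1]
        t_ant, t_post = ctrl_arc[proj[0]], ctrl_arc[proj[1]]
    # trim ridge points outside the anchor span; anchors become the termini
    interior = (ctrl_arc > t_ant) & (ctrl_arc < t_post)
    control = np.vstack([ant, control[interior], post])
    return control, (ant.copy(), post.copy())


def fit_axis_curve(
    control_points: np.ndarray,
    anchors: tuple[np.ndarray, np.ndarray] | None = None,
    n_polyline: int = 10000,
    extension_frac: float = 0.1,
    check_self_intersection: bool = True,
) -> AxisCurve:
    """Interpolating cubic spline through the control points, arc-length
    discretized into ``n_polyline`` evenly spaced points.

    Two extension points are appended by linear extrapolation of the terminal
    tangents (each ``extension_frac`` of the curve length); positions are
    cumulative arc length from the anterior end of the extended curve, and
    polyline points on the extensions are marked.
    """
    control_points = np.asarray(control_points, dtype=float)
    if len(control_points) < 4:
        raise ValueError("need at least 4 control points for a spline")
    if n_polyline < 2:
        raise ValueError("n_polyline must be >= 2")
    chord = _polyline_arclength(control_points)
    if np.any(np.diff(chord) <= 0):
        raise ValueError("control points contain consecutive duplicates")
    spl_x = CubicSpline(chord, control_points[:, 0])
    spl_y = CubicSpline(chord, control_points[:, 1])
    dense_t = np.linspace(0.0, chord[-1], max(4000, 4 * n_polyline))
    dense = np.column_stack([spl_x(dense_t), spl_y(dense_t)])
    main_len = _polyline_arclength(dense)[-1]

    ext_len = extension_frac * main_len
    tan0 = np.array([spl_x(0.0, 1), spl_y(0.0, 1)])
    tan1 = np.array([spl_x(chord[-1], 1), spl_y(chord[-1], 1)])
    tan0 /= np.linalg.norm(tan0)
    tan1 /= np.linalg.norm(tan1)
    ext_a = control_points[0] - tan0 * ext_len
    ext_p = control_points[-1] + tan1 * ext_len

    full = np.vstack([ext_a, dense, ext_p])
    arc = _polyline_arclength(full)
    total = arc[-1]
    even = np.linspace(0.0, total, n_polyline)
    polyline = np.column_stack(
        [np.interp(even, arc, full[:, 0]), np.interp(even, arc, full[:, 1])]
    )
    ant_term = arc[1]  # arc position of the first control point
    post_term = arc[-2]
    spacing = total / (n_polyline - 1)
    on_ext = (even < ant_term - 0.5 * spacing) | (even > post_term + 0.5 * spacing)

    if check_self_intersection:
        thin = polyline[:: max(1, n_polyline // 400)]
        tree = cKDTree(thin)
        pairs = tree.query_pairs(r=2.0 * spacing * max(1, n_polyline // 400))
        if any(abs(i - j) > 5 for i, j in pairs):
            warnings.warn(
                "axis spline may self-intersect; nearest-point positions "
                "remain well-defined",
                RuntimeWarning,
                stacklevel=2,
            )

    if anchors is None:
        anchors = (control_points[0], control_points[-1])
    return AxisCurve(
        control_points=control_points,
        anterior_anchor=np.asarray(anchors[0], dtype=float),
        posterior_anchor=np.asarray(anchors[1], dtype=float),
        extension_points=np.vstack([ext_a, ext_p]),
        polyline=polyline,
        positions=even,
        on_extension=on_ext,
        anterior_terminus=float(ant_term),
        posterior_terminus=float(post_term),
    )


def nearest_polyline_point(
    pts: np.ndarray, polyline: np.ndarray, tree: cKDTree | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest polyline point per query point; ties -> lowest index.

    Uses a k-d tree, then resolves near-ties deterministically so the result
    matches a brute-force scan over all polyline points.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if tree is None:
        tree = cKDTree(polyline)
    k = min(8, len(polyline))
    dist, idx = tree.query(pts, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best_idx = np.empty(len(pts), dtype=np.int64)
    best_dist = np.empty(len(pts))
    for i in range(len(pts)):
        d = dist[i]
        tie = d <= d[0] * (1.0 + 1e-12) + 1e-15
        best_idx[i] = idx[i][tie].min()
        best_dist[i] = d[0]
    return best_idx, best_dist


def assign_positions(
    emb: pd.DataFrame,
    curve: AxisCurve,
    axis_clusters: set[str] | list[str],
    nm: NormalizedMatrix | None = None,
    anterior_exclusion: tuple[list[str], float] | None = None,
    keep_omitted: bool = False,
) -> pd.DataFrame:
    """Assign each axis-cluster nucleus its arc-length position and distance.

    position = arc-length value of the nearest polyline point (exact nearest
    over all points), distance = Euclidean distance to it.  Nuclei whose
    nearest point lies on an extension segment sit beyond the termini and are
    omitted (kept, flagged, when ``keep_omitted``).  ``anterior_exclusion`` =
    (gene set, fraction): additionally drop nuclei within that fraction of
    the axis length from the anterior terminus that express none of the
    genes (the mode used when an anterior marker delimits the tissue).
    """
    axis_clusters = set(axis_clusters)
    if not axis_clusters:
        raise ValueError("axis_clusters must be non-empty")
    sel = emb[emb["cluster"].isin(axis_clusters)]
    if len(sel) == 0:
        raise ValueError("no nuclei in the requested axis clusters")
    pts = sel[["x", "y"]].to_numpy(dtype=float)
    idx, dist = nearest_polyline_point(pts, curve.polyline)
    table = pd.DataFrame(
        {
            "nucleus_id": sel["nucleus_id"].to_numpy(),
            "position": curve.positions[idx],
            "distance": dist,
            "on_extension": curve.on_extension[idx],
        }
    )
    if anterior_exclusion is not None:
        if nm is None:
            raise ValueError("anterior_exclusion requires the expression matrix")
        genes, frac = anterior_exclusion
        gi = nm.genes.get_indexer(genes)
        if np.any(gi < 0):
            raise ValueError("anterior_exclusion genes missing from matrix")
        bi = nm.barcodes.get_indexer(table["nucleus_id"])
        expr = np.asarray(nm.values[gi][:, bi].sum(axis=0)).ravel()
        near_ant = table["position"] < curve.anterior_terminus + frac * curve.axis_length
        table = table[~(near_ant.to_numpy() & (expr == 0))]
    if not keep_omitted:
        table = table[~table["on_extension"]].reset_index(drop=True)
    else:
        table = table.reset_index(drop=True)
    table.attrs["anterior_terminus"] = curve.anterior_terminus
    table.attrs["posterior_terminus"] = curve.posterior_terminus
    return table
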
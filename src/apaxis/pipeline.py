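"""End-to-end pipeline orchestration from a single strict config.

Stages: simulate (or load) -> QC -> normalize -> cluster/embed -> axis ->
profiles -> gene selection -> derivative analysis, with every random
operation seeded from the config and a manifest recording seeds, parameters,
and row/column counts at each stage so any output is regenerable from the
config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import axis as axis_mod
from . import clustering, derivatives, io_qc, profiles as profiles_mod, selection, synthetic

log = logging.getLogger("apaxis")


@dataclass
class SimulateConfig:
    n_ectoderm: int = 3000
    n_other: int = 600
    seed: int = 1
    curve_shape: str = "arc"
    noise_sd: float = 0.5
    panel_seed: int = 20260918


@dataclass
class QCConfig:
    preset: str | None = None  # stage7_cell | stage7_nucleus | latestage5_nucleus
    min_genes: int = 200
    max_molecules: int = 100000
    scale_factor: float = 1.0e4
    enabled: bool = True


@dataclass
class ClusterConfig:
    n_variable: int = 2000
    n_dims: int = 50
    resolution: float = 1.0
    seed: int = 0
    n_neighbors: int = 15
    embedding: str = "umap"
    enabled: bool = False  # synthetic runs ship their own embedding


@dataclass
class AxisConfig:
    anterior_genes: list[str] = field(default_factory=lambda: ["ancA0", "ancA1"])
    posterior_genes: list[str] = field(default_factory=lambda: ["ancP0", "ancP1"])
    manual_points_file: str | None = None
    n_polyline: int = 10000
    n_control: int = 12
    extension_frac: float = 0.1


@dataclass
class ProfileConfig:
    near_axis_threshold: float = 0.3
    span: float = 0.05
    grid_size: int = 160


@dataclass
class SelectConfig:
    k1: int = 12
    k2_min: int = 2
    k2_max: int = 5
    rule: str = "median"
    whitelist: list[str] | None = None


@dataclass
class AnalysisConfig:
    top_k: int = 50
    region_max_threshold: float = 0.2
    region_groups: dict[str, int] = field(
        default_factory=lambda: {"A": 6, "B": 6, "C": 6}
    )
    pair_window: list[int] = field(default_factory=lambda: [59, 72])
    pair_min_expr_frac: float = 0.10
    pair_r_threshold: float = 0.5


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    axis: AxisConfig = field(default_factory=AxisConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        out = cls()
        for section, payload in data.items():
            if not hasattr(out, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(out, section)
            if not isinstance(payload, dict):
                raise TypeError(f"config section {section!r} must be a mapping")
            for key, value in payload.items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(sub, key, value)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    input_matrix=None,
    input_embedding: pd.DataFrame | None = None,
) -> dict:
    """Execute the pipeline; write stage outputs and a manifest to outdir.

    Without an ``input_matrix`` the synthetic simulator provides counts,
    ground truth, and a mock embedding.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}}
    config.to_yaml(outdir / "config.yaml")

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        truth = None
        emb = input_embedding
        if input_matrix is None:
            info = stage("simulate")
            panel = synthetic.default_panel(config.simulate.panel_seed)
            cm, truth = synthetic.simulate_embryo(
                config.simulate.n_ectoderm,
                config.simulate.n_other,
                panel,
                seed=config.simulate.seed,
            )
            emb = synthetic.embed_ground_truth(
                truth,
                config.simulate.curve_shape,
                config.simulate.noise_sd,
                seed=config.simulate.seed,
            )
            synthetic.write_simulation(outdir / "sim", cm, truth, emb)
            info.update(
                {"n_genes": cm.shape[0], "n_nuclei": cm.shape[1], "seed": config.simulate.seed}
            )
        else:
            cm = input_matrix

        info = stage("qc")
        if config.qc.enabled:
            if config.qc.preset:
                min_g, max_m = io_qc.QC_PRESETS[config.qc.preset]
            else:
                min_g, max_m = config.qc.min_genes, config.qc.max_molecules
            cm, report = io_qc.qc_filter(cm, min_g, max_m)
            report.to_csv(outdir / "qc_removed.tsv", sep="\t", index=False)
            info.update(
                {"min_genes": min_g, "max_molecules": max_m, "n_removed": len(report),
                 "n_retained": cm.shape[1]}
            )
        nm = io_qc.log_normalize(cm, config.qc.scale_factor)

        info = stage("embedding")
        if emb is None or config.cluster.enabled:
            emb = clustering.reduce_and_cluster(
                nm,
                n_variable=config.cluster.n_variable,
                n_dims=min(config.cluster.n_dims, min(nm.shape) - 1),
                resolution=config.cluster.resolution,
                seed=config.cluster.seed,
                n_neighbors=config.cluster.n_neighbors,
                embedding=config.cluster.embedding,
            )
        emb = emb[emb["nucleus_id"].isin(set(nm.barcodes))].reset_index(drop=True)
        emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
        info.update({"n_nuclei": len(emb), "n_clusters": emb["cluster"].nunique()})

        info = stage("axis")
        axis_clusters = sorted(c for c in emb["cluster"].unique() if c != "other")
        manual = None
        if config.axis.manual_points_file:
            manual = np.loadtxt(config.axis.manual_points_file, delimiter="\t")
        control, anchors = axis_mod.extract_ridge_control_points(
            emb,
            axis_clusters,
            anchor_genes=(config.axis.anterior_genes, config.axis.posterior_genes),
            nm=nm,
            manual_points=manual,
            n_control=config.axis.n_control,
        )
        curve = axis_mod.fit_axis_curve(
            control,
            anchors,
            n_polyline=config.axis.n_polyline,
            extension_frac=config.axis.extension_frac,
        )
        pos = axis_mod.assign_positions(emb, curve, axis_clusters)
        (outdir / "axis_curve.json").write_text(json.dumps(curve.to_json_dict()))
        pos.to_csv(outdir / "positions.tsv", sep="\t", index=False)
        info.update(
            {"n_positioned": len(pos), "axis_length": curve.axis_length,
             "n_polyline": config.axis.n_polyline}
        )

        info = stage("profiles")
        params = profiles_mod.SmoothingParams(
            near_axis_threshold=config.profile.near_axis_threshold,
            span=config.profile.span,
            grid_size=config.profile.grid_size,
            trim_lo=config.profile.grid_size // 4 + 1,
            trim_hi=3 * config.profile.grid_size // 4,
        )
        near = profiles_mod.select_near_axis(pos, params.near_axis_threshold)
        prof = profiles_mod.build_profile_matrix(nm, near, params)
        prof.to_csv(outdir / "profiles.csv")
        info.update(
            {"n_near_axis": len(near), "n_profiles": len(prof),
             "n_positions": prof.shape[1]}
        )

        info = stage("selection")
        retained, excluded, gaps = selection.sparse_gene_filter(nm, pos)
        feats = selection.compute_pattern_features(prof.loc[retained])
        result = selection.two_round_select(
            feats,
            k1=config.select.k1,
            k2_range=(config.select.k2_min, config.select.k2_max),
            rule=config.select.rule,
            whitelist=set(config.select.whitelist) if config.select.whitelist else None,
        )
        result["excluded_sparse"] = False
        sparse_rows = pd.DataFrame(
            {"round1_group": 0, "round2_group": 0, "selected": False, "excluded_sparse": True},
            index=excluded,
        )
        full_result = pd.concat([result, sparse_rows])
        full_result.to_csv(outdir / "selection.tsv", sep="\t")
        selected = result.index[result["selected"]].tolist()
        info.update(
            {"n_sparse_excluded": len(excluded), "n_selected": len(selected)}
        )

        info = stage("derivatives")
        derivs = derivatives.first_derivative(prof)
        derivs.to_csv(outdir / "derivatives.csv")
        if selected:
            sel_derivs = derivs.loc[selected]
            extremes = derivatives.top_extremes_table(
                sel_derivs, k=min(config.analysis.top_k, len(selected))
            )
            extremes.to_csv(outdir / "derivative_extremes.tsv", sep="\t", index=False)
            posmap = derivatives.position_correlation(sel_derivs)
            posmap.to_csv(outdir / "position_correlation.csv")
            groups = {}
            for name, ng in config.analysis.region_groups.items():
                region = derivatives.DEFAULT_REGIONS[name]
                try:
                    grp = derivatives.region_gene_groups(
                        prof.loc[selected],
                        sel_derivs,
                        region,
                        n_groups=min(ng, max(2, len(selected) // 4)),
                        max_threshold=config.analysis.region_max_threshold,
                    )
                    groups[name] = grp
                except ValueError as exc:
                    log.warning("region %s grouping skipped: %s", name, exc)
            if groups:
                pd.DataFrame(groups).to_csv(outdir / "region_groups.tsv", sep="\t")
            edges = derivatives.gene_pair_network(
                nm,
                near,
                tuple(config.analysis.pair_window),
                selected,
                grid=prof.attrs["grid"],
                min_expr_frac=config.analysis.pair_min_expr_frac,
                r_threshold=config.analysis.pair_r_threshold,
            )
            edges.to_csv(outdir / "gene_pairs.tsv", sep="\t", index=False)
            info.update({"n_edges": len(edges), "regions": {k: int(v.nunique()) for k, v in groups.items()}})

        if truth is not None:
            info = stage("recovery")
            from .perturb import axis_recovery_score

            score = axis_recovery_score(
                pos, truth.nuclei[["nucleus_id", "u"]].dropna()
            )
            info.update({"global_rho": score.global_rho})
    except Exception as exc:
        failed = next(reversed(manifest["stages"]), "?")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
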
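"""Synthetic germ-band simulator with known ground truth.

Emulates the statistical structure the axis-reconstruction pipeline assumes:
ectoderm nuclei carry a latent anterior-posterior coordinate u in [0, 1];
stripe genes follow bi-splitting / tri-splitting / oscillatory mean functions
of u; counts are negative-binomial with lognormal library sizes; and the
latent axis appears in 2-D as a noisy curve (the elongated ectoderm
supercluster seen in single-nucleus embeddings of the germ band).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

PATTERN_CLASSES = (
    "anterior_gradient",
    "posterior_gradient",
    "regional_block",
    "bi_split",
    "tri_split",
    "oscillatory",
    "terminal_anchor_A",
    "terminal_anchor_P",
    "uniform",
    "sparse_noise",
)

#: classes whose mean function depends on the latent position u
PATTERNED_CLASSES = frozenset(PATTERN_CLASSES) - {"uniform", "sparse_noise"}

#: posterior window within which oscillatory genes are active (u units);
#: the germ-band segmentation clock runs only in the posterior growth zone
OSC_WINDOW = (0.55, 1.0)


@dataclass
class StripeSpec:
    """Specification of one gene's expression program along the latent axis."""

    gene_id: str
    pattern_class: str
    peak_centers: tuple[float, ...] = ()
    peak_width: float = 0.04
    period: float = 0.125
    phase: float = 0.0
    amplitude: float = 0.0
    baseline: float = 0.0
    dispersion: float = 2.0
    sparse_fraction: float = 0.0
    window: tuple[float, float] = OSC_WINDOW
    osc_exponent: float = 2.0

    def validate(self) -> None:
        pc = self.pattern_class
        if pc not in PATTERN_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown pattern_class {pc!r}")
        if any(not (0.0 <= c <= 1.0) for c in self.peak_centers):
            raise ValueError(f"{self.gene_id}: peak_centers must lie in [0, 1]")
        if pc == "oscillatory" and self.period <= 0:
            raise ValueError(f"{self.gene_id}: oscillatory period must be > 0")
        if pc == "bi_split" and len(self.peak_centers) != 2:
            raise ValueError(f"{self.gene_id}: bi_split needs exactly 2 peak_centers")
        if pc == "tri_split" and len(self.peak_centers) != 3:
            raise ValueError(f"{self.gene_id}: tri_split needs exactly 3 peak_centers")
        if pc != "sparse_noise" and self.amplitude + self.baseline <= 0:
            raise ValueError(f"{self.gene_id}: amplitude + baseline must be > 0")
        if pc == "sparse_noise" and not (0.0 <= self.sparse_fraction <= 1.0):
            raise ValueError(f"{self.gene_id}: sparse_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError(f"{self.gene_id}: dispersion must be > 0")

    @property
    def is_patterned(self) -> bool:
        return self.pattern_class in PATTERNED_CLASSES

    def mean_function(self, u: np.ndarray) -> np.ndarray:
        """Expected count lambda(u) at unit library size."""
        u = np.asarray(u, dtype=float)
        pc = self.pattern_class
        a, b, w = self.amplitude, self.baseline, self.peak_width
        if pc == "uniform":
            return np.full_like(u, b + a)
        if pc == "sparse_noise":
            # position-independent; expression handled by the simulator
            return np.zeros_like(u)
        if pc == "anterior_gradient":
            return b + a * np.exp(-u / w)
        if pc == "posterior_gradient":
            return b + a * np.exp(-(1.0 - u) / w)
        if pc == "oscillatory":
            lo, hi = self.window
            bump = np.clip(
                np.cos(2.0 * np.pi * (u - self.phase) / self.period), 0.0, None
            ) ** self.osc_exponent
            lam = b + a * bump
            return np.where((u >= lo) & (u <= hi), lam, 0.0)
        # Gaussian bumps: regional blocks, split stripes, terminal anchors
        lam = np.zeros_like(u)
        for c in self.peak_centers:
            lam += np.exp(-0.5 * ((u - c) / w) ** 2)
        return b + a * lam


@dataclass
class GroundTruth:
    """Latent state of a simulated embryo: one row per nucleus plus the panel."""

    nuclei: pd.DataFrame  # nucleus_id, u, tissue, library_size
    stripe_specs: list[StripeSpec]
    rng_seed: int

    def __post_init__(self) -> None:
        if self.nuclei["nucleus_id"].duplicated().any():
            raise ValueError("duplicate nucleus IDs in ground truth")
        ect = self.nuclei["tissue"] == "ectoderm"
        if self.nuclei.loc[ect, "u"].isna().any():
            raise ValueError("ectoderm nuclei must all have a latent position")

    @property
    def ectoderm(self) -> pd.DataFrame:
        return self.nuclei[self.nuclei["tissue"] == "ectoderm"]

    def genes_of(self, *classes: str) -> list[str]:
        return [s.gene_id for s in self.stripe_specs if s.pattern_class in classes]

    @property
    def patterned_genes(self) -> list[str]:
        return [s.gene_id for s in self.stripe_specs if s.is_patterned]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "nuclei": self.nuclei.to_dict(orient="list"),
            "stripe_specs": [asdict(s) for s in self.stripe_specs],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        specs = []
        for d in payload["stripe_specs"]:
            d["peak_centers"] = tuple(d["peak_centers"])
            d["window"] = tuple(d["window"])
            specs.append(StripeSpec(**d))
        return cls(pd.DataFrame(payload["nuclei"]), specs, payload["rng_seed"])


def default_panel(seed: int = 20260918) -> list[StripeSpec]:
    """The default gene panel: 40 patterned, 400 uniform, 60 sparse-noise genes.

    Patterned genes emulate the germ-band repertoire: 8 bi-splitting head
    stripes (2 peaks each), 6 tri-splitting thoracic stripes, 10 oscillatory
    posterior genes in two antiphase classes (segmentation-clock analogs of
    the hh/msx1 complementarity), 8 regional head/thorax/opisthosoma blocks,
    2+2 terminal anchor markers, and 2+2 terminal gradients.  Uniform genes
    form the unpatterned transcriptome background with lognormal baseline
    levels; sparse-noise genes are detected in only a handful of nuclei,
    scattered independently of position.
    """
    rng = np.random.default_rng(seed)
    panel: list[StripeSpec] = []

    for i in range(8):  # bi-splitting head stripes
        c = 0.08 + 0.03 * i
        panel.append(
            StripeSpec(
                f"bi{i:02d}", "bi_split", peak_centers=(c, c + 0.09),
                peak_width=0.035, amplitude=6.0, baseline=0.05,
            )
        )
    for i in range(6):  # tri-splitting thoracic stripes
        c = 0.32 + 0.025 * i
        panel.append(
            StripeSpec(
                f"tri{i:02d}", "tri_split",
                peak_centers=(c, c + 0.08, c + 0.16),
                peak_width=0.03, amplitude=6.0, baseline=0.05,
            )
        )
    for i in range(10):  # oscillatory posterior genes, two antiphase classes
        phase = 0.0 if i < 5 else 0.0625
        panel.append(
            StripeSpec(
                f"osc{i:02d}", "oscillatory", period=0.125, phase=phase,
                amplitude=6.0, baseline=0.1,
            )
        )
    # broad regional blocks tiling the axis, like a Hox-style code: three
    # head/thorax/opisthosoma landmarks plus staggered intermediate domains
    region_centers = np.linspace(0.1, 0.9, 8)
    region_names = [
        "head", "head", "thorax", "thorax", "thorax", "opistho", "opistho", "opistho",
    ]
    for i, (name, c) in enumerate(zip(region_names, region_centers)):
        panel.append(
            StripeSpec(
                f"reg{i:02d}_{name}", "regional_block", peak_centers=(float(c),),
                peak_width=0.1, amplitude=4.0, baseline=0.1,
            )
        )
    for i in range(2):
        panel.append(
            StripeSpec(
                f"ancA{i}", "terminal_anchor_A", peak_centers=(0.02,),
                peak_width=0.04, amplitude=6.0, baseline=0.02,
            )
        )
        panel.append(
            StripeSpec(
                f"ancP{i}", "terminal_anchor_P", peak_centers=(0.98,),
                peak_width=0.04, amplitude=6.0, baseline=0.02,
            )
        )
        panel.append(
            StripeSpec(
                f"grad{i}_ant", "anterior_gradient", peak_width=0.25,
                amplitude=5.0, baseline=0.05,
            )
        )
        panel.append(
            StripeSpec(
                f"grad{i}_post", "posterior_gradient", peak_width=0.25,
                amplitude=5.0, baseline=0.05,
            )
        )
    baselines = np.exp(rng.normal(np.log(1.5), 1.0, size=400))
    for i, b in enumerate(baselines):
        panel.append(
            StripeSpec(f"uni{i:03d}", "uniform", baseline=float(b))
        )
    # detection-floor noise genes: present in at most a few nuclei per embryo
    fracs = rng.uniform(5e-5, 3e-4, size=60)
    for i, f in enumerate(fracs):
        panel.append(
            StripeSpec(
                f"sparse{i:02d}", "sparse_noise", amplitude=4.0,
                sparse_fraction=float(f),
            )
        )
    return panel


def simulate_embryo(
    n_ectoderm: int,
    n_other: int,
    gene_panel: list[StripeSpec],
    seed: int,
    library_sigma: float = 0.35,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a count matrix and its ground truth from the generative model.

    Ectoderm nuclei receive u ~ Uniform(0, 1); the mean count of gene g in
    nucleus i is s_i * lambda_g(u_i) with s_i lognormal (sigma =
    ``library_sigma``, normalized to unit mean); counts are negative binomial
    with the spec's size parameter (``dispersion = inf`` gives Poisson).
    "Other" (non-ectoderm) nuclei follow a distinct non-axial program: zero
    for patterned genes, gene-specific lognormal multipliers of the baseline
    for uniform genes.  Fully reproducible from ``seed``.
    """
    if n_ectoderm < 10:
        raise ValueError("n_ectoderm must be >= 10")
    if not gene_panel:
        raise ValueError("gene_panel must be non-empty")
    seen = set()
    for s in gene_panel:
        s.validate()
        if s.gene_id in seen:
            raise ValueError(f"duplicate gene_id {s.gene_id!r} in panel")
        seen.add(s.gene_id)

    rng = np.random.default_rng(seed)
    n = n_ectoderm + n_other
    u_ect = rng.uniform(0.0, 1.0, size=n_ectoderm)
    u = np.concatenate([u_ect, np.full(n_other, np.nan)])
    tissue = np.array(["ectoderm"] * n_ectoderm + ["other"] * n_other)
    s_lib = np.exp(rng.normal(0.0, library_sigma, size=n))
    if s_lib.mean() > 0:
        s_lib = s_lib / s_lib.mean()

    # fixed per-gene program multipliers for the non-axial population
    other_factor = {
        spec.gene_id: float(np.exp(rng.normal(0.0, 0.7)))
        for spec in gene_panel
    }

    counts = np.zeros((len(gene_panel), n), dtype=np.int64)
    ect = tissue == "ectoderm"
    for gi, spec in enumerate(gene_panel):
        mu = np.zeros(n)
        if spec.pattern_class == "sparse_noise":
            on = rng.random(n) < spec.sparse_fraction
            mu[on] = spec.amplitude * s_lib[on]
        else:
            mu[ect] = s_lib[ect] * spec.mean_function(u[ect])
            if spec.pattern_class == "uniform":
                mu[~ect] = s_lib[~ect] * (
                    (spec.baseline + spec.amplitude) * other_factor[spec.gene_id]
                )
            # patterned genes silent in the non-axial population
        if np.isinf(spec.dispersion):
            counts[gi] = rng.poisson(mu)
        else:
            lam = rng.gamma(spec.dispersion, mu / spec.dispersion)
            counts[gi] = rng.poisson(lam)

    barcodes = pd.Index([f"N{i:05d}" for i in range(n)], name="barcode")
    genes = pd.Index([s.gene_id for s in gene_panel], name="gene_id")
    cm = CountMatrix(genes, barcodes, sp.csr_matrix(counts))
    truth = GroundTruth(
        pd.DataFrame(
            {
                "nucleus_id": barcodes.to_numpy(),
                "u": u,
                "tissue": tissue,
                "library_size": s_lib,
            }
        ),
        list(gene_panel),
        seed,
    )
    return cm, truth


CURVE_SHAPES = ("line", "arc", "s_curve")


def _curve_map(shape: str, u: np.ndarray, scale: float) -> np.ndarray:
    """Parametric planar curve gamma(u), length ~= ``scale`` embedding units."""
    if shape == "line":
        return np.column_stack([scale * u, np.zeros_like(u)])
    if shape == "arc":
        theta_span = 5.0 * np.pi / 6.0  # 150 degrees: elongated, curved
        r = scale / theta_span
        theta = (u - 0.5) * theta_span
        return np.column_stack([r * np.sin(theta), r * np.cos(theta)])
    if shape == "s_curve":
        x = scale * u
        y = 0.12 * scale * np.sin(2.0 * np.pi * u)
        return np.column_stack([x, y])
    raise ValueError(f"unknown curve_shape {shape!r}")


def embed_ground_truth(
    truth: GroundTruth,
    curve_shape: str = "arc",
    noise_sd: float = 0.5,
    seed: int = 0,
    n_cluster_bins: int = 6,
    scale: float = 10.0,
) -> pd.DataFrame:
    """Map latent positions onto a noisy planar curve (a mock 2-D embedding).

    Ectoderm nuclei land on gamma(u) plus isotropic Gaussian noise; "other"
    nuclei form a separate blob.  Cluster labels bin u into
    ``n_cluster_bins`` equal-width bins (labels ``e0..``), emulating the
    axially aligned ectoderm clusters; the blob is labelled ``other``.
    """
    if curve_shape not in CURVE_SHAPES:
        raise ValueError(f"unknown curve_shape {curve_shape!r}")
    ect = truth.ectoderm
    if len(ect) == 0:
        raise ValueError("ground truth has no ectoderm nuclei")
    rng = np.random.default_rng(seed)
    u = ect["u"].to_numpy()
    xy = _curve_map(curve_shape, u, scale)
    xy = xy + rng.normal(0.0, noise_sd, size=xy.shape)
    bins = np.minimum((u * n_cluster_bins).astype(int), n_cluster_bins - 1)
    cluster = np.array([f"e{b}" for b in bins], dtype=object)

    other = truth.nuclei[truth.nuclei["tissue"] != "ectoderm"]
    if len(other):
        center = xy.mean(axis=0) + np.array([0.0, 0.6 * scale])
        oxy = center + rng.normal(0.0, 0.05 * scale, size=(len(other), 2))
        xy = np.vstack([xy, oxy])
        cluster = np.concatenate([cluster, np.full(len(other), "other")])
    ids = np.concatenate([ect["nucleus_id"].to_numpy(), other["nucleus_id"].to_numpy()])
    emb = pd.DataFrame({"nucleus_id": ids, "x": xy[:, 0], "y": xy[:, 1], "cluster": cluster})
    emb.attrs["curve_shape"] = curve_shape
    emb.attrs["scale"] = scale
    return emb


def write_simulation(
    outdir: str | Path, cm: CountMatrix, truth: GroundTruth, emb: pd.DataFrame | None = None
) -> None:
    """Write matrix (MatrixMarket triplet), ground-truth sidecar, and embedding."""
    from .io_qc import write_count_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(cm, outdir)
    truth.to_json(outdir / "ground_truth.json")
    if emb is not None:
        emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
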
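# apaxis

Pseudospatial anterior–posterior (AP) axis reconstruction and stripe-gene
mining from single-nucleus RNA-seq embeddings.

## The problem

In single-nucleus RNA-seq of an elongating embryo (the motivating system is
the spider germ band at the stage when segmentation stripes form), the
ectoderm nuclei of a 2-D UMAP embedding line up in a long band that
recapitulates the embryo's AP axis: anterior cell states at one end,
posterior at the other, segmental stripe genes expressed in discrete domains
along it. `apaxis` turns that qualitative observation into a quantitative
instrument:

1. **Axis reconstruction** — trace the density ridge of the elongated
   ectoderm supercluster with a principal curve (or accept manually placed
   control points), orient it from an anterior to a posterior anchor defined
   by terminal marker genes, fit an interpolating cubic spline, extend it
   past both termini, discretize it into 10,000 evenly spaced arc-length
   points, and assign every nucleus the position of (and distance to) its
   nearest point. Nuclei beyond the termini are omitted.
2. **Expression profiles** — select nuclei within 0.3 embedding units of the
   curve, mirror their positions at both termini (suppressing loess edge
   bias), smooth each gene with loess (span 0.05, local quadratic, tricube
   weights) on a 160-point grid, and keep the central 80 points: a
   genome-wide matrix of expression at 80 AP subdivisions.
3. **Pattern-gene selection** — exclude genes detected only in a handful of
   scattered nuclei (two-group Ward clustering of the minimum
   inter-expressing-nucleus distance), then select stripe/region genes by
   two rounds of Ward clustering on each profile's (mean, max − min).
4. **Derivative analysis** — first-derivative profiles
   (d<sub>i</sub> = (x<sub>i+1</sub> − x<sub>i−1</sub>)/2 inside, one-sided at the termini),
   per-position extreme tables, position × position and gene × gene Pearson
   correlation maps (the segmentation clock appears as a periodic
   off-diagonal band), region-wise gene groups, and single-nucleus
   co-expression networks within position windows.
5. **Perturbation experiments** — where does the axial information live?
   Re-embed using only the selected genes (submatrix A) versus everything
   else (submatrix B), or permute the selected genes' values within one
   cluster (wholly or for a graded fraction of nuclei) and measure the local
   loss of axis continuity.

Because the original analysis depends on deposited data and manual spline
placement, the package ships a **synthetic germ-band simulator** with known
ground truth: nuclei carry a latent position u ∈ [0,1]; bi-splitting,
tri-splitting, oscillatory, regional, terminal-anchor, and gradient genes
follow stated mean functions of u; counts are negative-binomial with
lognormal library sizes; and the latent axis is embedded as a noisy planar
curve. Every pipeline stage can therefore be scored against truth.

## Worked example

```python
import apaxis as ap

panel = ap.default_panel()                    # 40 patterned + 400 uniform + 60 sparse genes
counts, truth = ap.simulate_embryo(n_ectoderm=3000, n_other=600,
                                   gene_panel=panel, seed=1)
embedding = ap.embed_ground_truth(truth, "arc", noise_sd=0.5, seed=1)
norm = ap.log_normalize(counts)

axis_clusters = [c for c in embedding["cluster"].unique() if c != "other"]
control, anchors = ap.extract_ridge_control_points(
    embedding, axis_clusters,
    anchor_genes=(["ancA0", "ancA1"], ["ancP0", "ancP1"]), nm=norm)
curve = ap.fit_axis_curve(control, anchors, n_polyline=10000)
positions = ap.assign_positions(embedding, curve, axis_clusters)
print(f"{len(positions)} nuclei positioned on a {curve.axis_length:.2f}-unit axis")

near = ap.select_near_axis(positions, threshold=0.3)
profiles = ap.build_profile_matrix(norm, near)

retained, excluded, gaps = ap.sparse_gene_filter(norm, positions)
features = ap.compute_pattern_features(profiles.loc[retained])
result = ap.two_round_select(features)
selected = result.index[result["selected"]]
print(f"sparse filter removed {len(excluded)} genes; "
      f"two-round clustering selected {len(selected)} pattern genes")

score = ap.axis_recovery_score(positions, truth.nuclei[["nucleus_id", "u"]].dropna())
print(f"axis recovery vs latent truth: |rho| = {score.global_rho:.3f}")
```

prints

```
2640 nuclei positioned on a 8.61-unit axis
sparse filter removed 56 genes; two-round clustering selected 40 pattern genes
axis recovery vs latent truth: |rho| = 0.982
```

360 of the 3000 ectoderm nuclei fell beyond the terminal anchors and were
omitted; the 80-column profile matrix covers all 500 genes; the sparse
filter caught the 56 detection-floor noise genes present in this draw, and
the selection recovered exactly the 40 genes simulated with patterned mean
functions. The Spearman magnitude of 0.98 between assigned arc-length
positions and the hidden latent coordinate is the headline check that the
reconstructed axis is the embryo's axis.

A CLI mirrors the stages (`apaxis simulate | qc | cluster | markers | axis |
profiles | select | derive | posmap | groups | pairs | perturb |
submatrix-test | run`); `apaxis run --config cfg.yaml --outdir out/` drives
everything from one strictly validated YAML config and writes a manifest
with seeds and per-stage counts.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete synthetic pipeline from scratch — simulation, QC,
normalization, axis reconstruction, genome-wide profiling, sparse-gene
exclusion, two-round selection, and derivative analysis — seeded by
`--seed`, prints a one-line summary of the run to stderr, and writes the
results JSON to `--out`.

## Layout

| Module | Contents |
| --- | --- |
| `apaxis.synthetic` | stripe specifications, embryo simulator, mock embeddings |
| `apaxis.io_qc` | MatrixMarket/CSV IO, QC presets, log-normalization |
| `apaxis.clustering` | variable features, PCA, Leiden, UMAP, markers, subsampling |
| `apaxis.axis` | principal-curve ridge tracing, spline fitting, position assignment |
| `apaxis.profiles` | near-axis selection, mirroring, loess profile matrix |
| `apaxis.selection` | sparse-gene filter, (mean, diff) two-round selection, submatrices |
| `apaxis.derivatives` | derivative profiles, correlation maps, region groups, networks |
| `apaxis.perturb` | in-cluster randomization, recovery scoring, sweep harnesses |
| `apaxis.pipeline` / `apaxis.cli` | config-driven orchestration and the CLI |

See `docs/methods.md` for the model, parameter defaults, and limitations.
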
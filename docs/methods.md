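# Methods

This note documents the models and procedures implemented in `apaxis`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a user re-tuning the pipeline
should know about.

## 1. The pseudospatial model

The working assumption is that the ectoderm of an elongating embryo forms a
one-dimensional continuum of cell states parameterized by AP position, and
that a 2-D embedding of single-nucleus transcriptomes places that continuum
on a smooth curve with transverse scatter. Position along the curve is then
a proxy for anatomical position, and smoothing expression against it yields
spatial expression profiles without any imaging.

Assumptions this rests on:

- the axial clusters contain one dominant 1-D signal (no branching; no
  second spatial axis strong enough to bend the manifold);
- terminal identities are marked by genes expressed only at the anterior or
  posterior end, which orient the otherwise direction-free curve;
- the embedding's local geometry is meaningful at the scale of the
  transverse scatter (positions are read off at nearest-point resolution).

## 2. Axis reconstruction

**Ridge tracing.** The original procedure placed control points by hand on
the density-contour ridge of the ectoderm supercluster. The automatic
default here is a principal curve: initialize the latent parameter with the
first principal axis, iterate (loess-smooth each coordinate against the
parameter → project points onto the smoothed curve → re-parameterize by arc
length) to convergence, then sample control points at even arc-length
quantiles and nudge each along its local normal to the kernel-density
maximum (Gaussian weights, Scott's-rule bandwidth). Manual control points
remain available (`manual_points=`) and are used verbatim, which reproduces
the human-in-the-loop mode exactly.

Failure is detected, not hidden: if the traced curve folds repeatedly
through the cloud (curve length > 1.8× the cloud's bounding diagonal) or is
short relative to the transverse spread (length < 2 × 4·median
perpendicular distance), a `RidgeError` reports that no elongated component
exists. The folding test catches isotropic blobs, through which an
unconstrained principal curve happily snakes; both thresholds are exposed.

**Anchors.** The anterior (posterior) anchor is the location of the maximum
kernel density estimate over nuclei expressing the anterior (posterior)
marker set; an anchor supported by fewer than 5 expressing nuclei is
rejected as ill-defined. Control points outside the anchor span are
trimmed, so the anchors are the curve termini.

**Spline and discretization.** An interpolating cubic spline
(chord-length parameterized, natural boundary) passes through the control
points; two extension points continue the terminal tangents by 10% of the
curve length each (configurable). The extended curve is resampled to
`n_polyline` (default 10,000) points evenly spaced in arc length;
positions are cumulative arc length from the anterior end. The extensions
exist so that distances near the termini are measured correctly; a nucleus
whose nearest polyline point lies on an extension is "more anterior or
posterior than the ends" and is omitted (the nearest-point membership test
realizes that rule with no separate geometry).

**Assignment.** Nearest-point search uses a k-d tree but is contractually
exact: near-ties are resolved to the lowest polyline index, and the test
suite checks exact agreement with a brute-force scan over all 10,000
points. Positions and distances are invariant under rigid motions of the
embedding to ~1e-8 (verified).

## 3. Expression profiles

Nuclei within 0.3 embedding units of the curve (inclusive) are selected.
The threshold is in embedding units: it was tuned for the original UMAP's
scale and **must be revisited for any differently scaled embedding**; it is
the most prominent knob in the config.

Positions are then mirrored: with termini a < b and midpoint c, nuclei at
p ≤ c gain a copy at 2a − p, nuclei at p > c a copy at 2b − p. Mirroring
makes the data locally even about each terminus, which cancels the
first-order boundary bias of local regression — the test suite verifies
that an even function's smoothed profile has vanishing terminal slope.

Each gene is smoothed by loess — local quadratic, tricube weights, span
0.05 (fraction of the doubled points) — evaluated on a 160-point grid
spanning exactly the mirrored range; points 41–120 (the original [a, b])
are kept and re-indexed as subdivisions 1–80. Because loess with a fixed
design is a linear smoother, the 160 × n smoother matrix is materialized
once and applied to all genes as a single sparse–dense product; an all-zero
gene automatically yields an all-zero profile. Negative loess outputs are
kept (clipping would bias the derivative analysis). Exact position ties
(mirror fixed points) are broken by an infinitesimal (1e-10 axis-length)
jitter before the smoother is built.

The effective smoothing window is ~0.05 × the doubled axis ≈ 8
subdivisions, which bounds the finest resolvable pattern: features narrower
than ~4 subdivisions are strongly attenuated.

## 4. Gene selection

**Sparse filter.** For each gene, the minimum |Δposition| between
expressing nuclei (sentinel: the full axis length when fewer than two
express it); Ward clustering (scipy `ward`, equivalent to R's `ward.D2` on
Euclidean distances) of that scalar into two groups; the larger-mean group
is excluded. With the sentinel convention the cut isolates the
detection-floor class — genes detected in ≲2 nuclei — which is the class
the filter is meant to remove.

**Two-round selection.** Features per gene: mean and max − min ("diff") of
the 80 profile values, z-scored (toggleable) before Ward clustering into
k1 = 12 groups. The published criterion — "relatively low mean, large
difference" — was a human judgment; the codified default is:

> keep a group iff its centroid mean < grand median of means **and** its
> centroid diff > grand median of diffs + 2.0 × MAD of diffs.

The MAD margin is the operative codification of "relatively large". Without
it, the rule fails on its own reference cases: Ward slices an unpatterned
cloud by mean, and such slices sit above the raw diff median about half the
time (loess wiggle also makes a uniform gene's diff grow with its mean, so
whole near-median groups can pass). A 5-world calibration sweep showed
sensitivity 1.0 for margins 1–3 and ≤1% uniform false selection for margins
≥ 2; 2.0 is the default, set once. Kept groups are re-clustered into 2–5
subgroups (k by maximum silhouette, ties to smaller k) and subgroups face
the same rule; a whitelist mode (`rule="whitelist"`) replaces the rule for
exact replication of a manual choice. Subgroup labels are computed for
unselected groups too, since the original analysis did the same.

## 5. Derivative analysis

First derivatives: central difference (x[i+1] − x[i−1])/2 at subdivisions
2–79 and one-sided differences at 1 and 80. The verbal definition of the
interior formula ("average difference between the current position and its
two neighboring positions") is sign-ambiguous; the central difference is
the only reading consistent with a first derivative, and the terminal signs
are oriented to match (positive = increasing toward posterior). Position ×
position correlation maps treat positions as variables and genes as
observations; zero-variance positions yield missing entries (never
imputed). Region grouping (defaults A = 1–33, B = 28–58, C = 55–80)
filters genes whose in-region profile maximum is below 0.2 (strict),
computes the gene × gene Pearson map of in-region derivatives, and applies
Ward clustering to the Euclidean distances between the correlation matrix's
rows (the "distances from the correlation coefficients" idiom; a
√(2(1−r)) metric is selectable). The number of groups is a required
argument — the original counts (27/33/29) came with no stated cut rule, so
no default is pretended. Single-nucleus networks select nuclei in a closed
subdivision window (a boundary subdivision shared by two windows belongs to
both), drop genes expressed in ≤10% of them (strict "more than"), and emit
gene pairs with |r| > 0.5.

## 6. Perturbation experiments and scoring

Randomization permutes each target gene's values independently among the
nuclei of one cluster; with fraction f < 1, an independent subset of ⌈f·n⌉
cluster nuclei is drawn per gene and only those values are permuted.
Conservation is absolute and tested bitwise: per-gene within-cluster value
multisets, all out-of-cluster values, and all non-target genes are
unchanged.

The published readout of these experiments was visual ("the alignment
became discontinuous at the modified cluster"). This package scores it:

- `global_rho`: |Spearman ρ| between recovered and reference positions
  (absolute value because a fresh embedding has no intrinsic orientation);
- `continuity`: per cluster, the mean fraction of each nucleus's k nearest
  embedding neighbors (default k = 30) that are also among its k nearest
  neighbors along the reference axis.

Both metrics are this package's operationalization and are labelled as such.
Re-embedding after a perturbation reuses the seed of the unperturbed run,
so score differences reflect the perturbation, not embedding stochasticity.
For scoring an embedding, 1-D positions are produced by the automatic axis
pipeline; when no elongated ridge exists (e.g. submatrix B collapses the
axis), scoring falls back to raw principal-curve arc positions so that a
failed reconstruction yields a low score rather than an exception.

## 7. The synthetic germ band

`simulate_embryo` draws, for each ectoderm nucleus, u ~ Uniform(0,1) and a
lognormal library factor s (σ = 0.35, normalized to unit mean); gene g's
count is negative binomial with mean s·λ_g(u) and size θ (default 2,
typical single-nucleus overdispersion; θ = ∞ gives Poisson). Mean
functions λ:

| class | form | defaults |
| --- | --- | --- |
| bi/tri_split | Gaussian bumps at 2/3 peak centers | width 0.03–0.035, amplitude 6 |
| oscillatory | baseline + amp·max(0, cos 2π(u−φ)/T)², inside window | T = 0.125, window (0.55, 1), two phase classes φ = 0, T/2 |
| regional_block | one broad Gaussian | width 0.1, amplitude 4, centers tiling 0.1–0.9 |
| terminal anchors | bump at u = 0.02 / 0.98 | width 0.04 |
| gradients | exp decay from either end | decay length 0.25 |
| uniform | constant baseline | lognormal(ln 1.5, 1) across genes |
| sparse_noise | amplitude in a random nucleus subset, u-independent | fraction U(5e-5, 3e-4) |

The squared-cosine clock gives distinct peak/trough phases for the two
phase classes (the complementary stripe pairs seen in segmenting embryos);
the exponent is configurable. Regional blocks tile the axis like a
Hox-style code, which also gives the posterior monotone positional
information alongside the periodic clock — without it a 2-D embedding of
the panel coils the posterior, since a purely periodic code cannot order
positions one period apart. Sparse-noise fractions put genes at the
detection floor (0–2 expressing nuclei at desk scale), the class the
sparse filter exists to remove. "Other" (non-ectoderm) nuclei express
patterned genes at zero and uniform genes through fixed per-gene lognormal
multipliers — a distinct, non-axial program.

`embed_ground_truth` maps u onto a line, a 150° arc, or an S-curve of
length ~10 embedding units plus isotropic Gaussian noise, bins u into
equal-width cluster labels (default 6), and places "other" nuclei in a
displaced blob.

**What a green test establishes — and what it does not.** The generator
emulates: counts with realistic overdispersion and library-size variation,
a curved noisy 1-D manifold, terminal markers, a segmentation-clock
wavelength near the smoothing resolution, and a large unpatterned
background. It does not emulate: doublets, ambient RNA, batch effects,
nonuniform nucleus density along the axis, u-dependent capture efficiency,
branching manifolds, or a second (dorsoventral) axis. Recovery statistics
on this world validate the machinery, not the biology of any particular
dataset.

A note on noise regimes: tangential positional noise σ (in latent units)
attenuates a period-T signal in the profiles by exp(−(2πσ/T)²/2). At the
axis-recovery noise level (5% of curve length, σ ≈ 0.046) the default
clock (T = 0.125) is attenuated ~14-fold — position recovery still
succeeds, but periodicity detection is run on a lower-noise world (1.5%,
attenuation ~0.78), matching the regime in which stripes are visibly
resolved in real embeddings.

## 8. QC, normalization, clustering defaults

Nucleus filters are strict inequalities — more than `min_genes` detected
genes and fewer than `max_molecules` molecules — with presets
stage7_cell (1500, 20000), stage7_nucleus (2000, 20000), and
latestage5_nucleus (1500, 15000). "Detected genes" counts genes with count
> 0. Normalization is ln(1 + 10⁴·count/total), natural log (the base is
unstated upstream; natural log is the convention of the toolkit the
procedure came from). Clustering delegates to scanpy: dispersion-ranked
variable features (default 2000), per-gene scaling capped at 10, PCA
(arpack), SNN graph, Leiden (igraph flavor; the original toolkit used
Louvain — both are modularity optimizers and Leiden is the ecosystem's
current default), UMAP with fixed seed. Markers: Wilcoxon rank-sum per
cluster vs rest, Bonferroni adjustment (the original toolkit's default;
Benjamini–Hochberg selectable), strict thresholds pct_in > 0.25,
pct_out < 0.90, adjusted p < 0.001. Pseudocluster diagnosis flags clusters
whose median gene and molecule counts both fall below 0.7 × the global
medians; flags are advisory.

## 9. Numerical details and degenerate inputs

- Loess windows contain at least degree + 2 points; boundary weights use
  h·(1+1e-9) so the farthest neighbor keeps zero weight without divide-by-
  zero; singular local fits fall back to pseudoinverse / lower degree.
- Polyline resampling is linear interpolation along a dense (≥4 ×
  n_polyline) spline evaluation; consecutive spacing is uniform to ≪1%.
- Self-intersecting splines warn but do not fail (nearest-point positions
  remain well-defined).
- Mirror midpoint ties go to the anterior half; profile/selection outputs
  are invariant to nucleus and gene order (tested).
- Empty QC results, zero-total columns, all-sparse gene sets, empty
  selections, sub-minimum clusters, and <10-nucleus windows raise
  informative errors rather than propagating NaNs.

## 10. Known limitations

- The near-axis threshold (0.3) and continuity k are scale/ density
  dependent; neither is dimensionless.
- The automatic ridge tracer assumes a single unbranched component; it will
  trace the dominant curve of a branched cloud without warning if the
  branch is small.
- Ward clustering of ~20k genes (full-genome scale) builds an O(n²)
  distance matrix (~1.6 GB at n = 20,000) — at genome scale run the sparse
  filter on a machine with memory to match, or pre-bin the scalar feature.
- The 160-point grid is assumed to span exactly the mirrored range
  (upstream behavior unstated); subdivision 1 therefore sits half a grid
  step inside the anterior terminus.
- `run_submatrix_experiment`'s fallback scoring (principal-curve positions)
  makes score_B a property of whatever 1-D structure survives in submatrix
  B's embedding; it is a lower bound on "no axis", not a proof of absence.
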
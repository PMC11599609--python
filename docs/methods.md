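# Methods

This note documents the models and procedures implemented in `boxtess`,
the parameters that matter, the numerical choices behind them, and what
the synthetic data can and cannot show about real carapaces. All lengths
are in mm; curvatures in mm⁻¹ (mean, CMS) and mm⁻² (Gaussian, CGS).

## From a label field to per-scute variables

**Input.** A 3D integer label field (0 = background, k = scute id) with
voxel spacing, as written by the segmentation of a microCT scan or by
the synthetic generator. World coordinates of voxel (i, j, k) are
`origin + (index + 0.5) · spacing`.

**Region-adjacency graph (RAG).** One node per scute at its voxel
centroid; an edge wherever two labels share at least `min_contact`
face-adjacent voxel pairs (6-connectivity; default 1). Corner and edge
contacts never count — abutting scutes meet along sutures, and face
contact is the conservative reading. Voxel quantization creates spurious
diagonal contacts where four scutes nearly meet at a point; since a
generic trivalent tessellation contains no 4-clique, the measurement
pass prunes each 4-clique by removing the weaker (fewest shared faces)
of its two longest edges (`build_rag(prune_nongeneric=True)`; off by
default so the raw contact definition stays testable against a
brute-force scan).

**Dual surface.** The RAG's mutually adjacent triples form triangles;
chordless 4-cycles whose edges are not already saturated by two
triangles are kept as quad faces (genuinely four-sided junctions —
splitting them with a synthetic diagonal would corrupt the rings of all
four scutes). The dual places one vertex per face (centroid) and one
polygon around every node whose incident faces form a closed ring; the
polygons are fan-triangulated, midpoint-subdivided three times, and
smoothed with an umbrella-operator Laplacian (10 iterations, relaxation
0.7 — the workflow parameters of the segmentation software the field
uses). Carapace surface area SA is the summed triangle area of this
surface; a scute's plane-based area is the area of its dual polygon
patch. Scutes whose ring is open — they border a carapace opening — get
the sentinel −1000, which removes them from all area-based analyses.

**Thickness and width.** Principal axes of the scute's voxel-coordinate
covariance; extents are peak-to-peak projections plus one voxel (the
voxels have extent; a switch disables the correction). Thickness is the
smallest extent, width the largest, aspect ratio their quotient (≤ 1 by
construction). For a scute wrapped over a carapace edge the cuboid
thickness includes part of the wrap — a property of the cuboid
definition, shared with any measurement of curved plates by bounding
boxes.

**Curvature.** CGS and CMS are the product and mean of the two principal
curvatures at the surface point nearest the scute center, from a local
Monge-quadric fit (outward normals: convex is positive). Two surfaces
are available. `surface_curvatures` fits on the smoothed dual surface —
fine for meshes given directly (sphere/cylinder/plane oracles pass at
5%), but on voxel-derived data the dual surface is built from mid-shell
scute centers: it cannot resolve a carapace edge whose radius is below
the scute spacing, and thick edge scutes pull their centroids into the
corner wedge, locally inverting the measured curvature. The full
measurement pass (`measure_specimen`) therefore fits on the **outer
isosurface of the voxel shell**: the labeled mask is morphologically
closed (EDT-based, capping the openings), hole-filled, and the isosurface
extracted by marching cubes on a Gaussian-smoothed indicator
(σ = 1.2 voxels), which removes the binary staircase and recovers
sub-voxel accuracy (sphere-shell oracle: CGS within 2%, interquartile
spread ~7% of the value). The fit neighborhood radius defaults to 2× the
median inter-center spacing and is configurable.

**Carapace dimensions.** PCA of the scute centers; length is the range
along PC1 (always the anteroposterior axis for carapace-like clouds);
of the PC2/PC3 ranges, height is the one better aligned with a supplied
dorsoventral axis hint, otherwise the larger range is reported as height
with a warning.

## Statistical sequence

1. **Scaling fits.** ln(y) on ln(SA) by OLS for carapace length, height,
   width and the per-specimen **medians** of each scute variable
   (medians, not means, because horn-like outlier scutes distort means).
   95% CIs from the t distribution. Scute counts use a Poisson GLM with
   log link and untransformed SA as predictor; the reported slope and CI
   are exponentiated back to the response scale, so 1.00 means
   size-independent counts. The GLM CI is a profile-likelihood scan
   (deviance cutoff at χ²₀.₉₅, intercept refitted with the slope fixed
   via an offset); Wald is available.
2. **Normalization and regions.** Each variable is size-corrected as
   y / SA^slope with its fitted exponent. Scutes with normalized
   CGS ≥ 5 (inclusive; configurable) are carapace-edge scutes, the rest
   flat-region scutes.
3. **Pooling test.** OLS of ln(median y) on ln(SA) × region over the
   stacked flat and edge medians; a non-significant interaction
   (α = 0.05) justifies one pooled exponent per variable. Under a shared
   exponent the test's type-I error is calibrated (≈5% at 1000
   replicates, checked in the suite). Degenerate fits (zero residual
   variance) return NaN with a warning.
4. **Shape frequencies.** Per-specimen proportions of k-neighbored
   scutes (k = 3…8, ≥9 pooled), denominator excluding opening scutes
   (their neighbor counts are incomparable — at least one side has no
   neighbor). A switch additionally excludes zero-area scutes.
5. **Multivariate analysis.** Drop scutes with area −1000 or 0;
   size-correct the seven dimensioned variables; natural-log everything
   except neighbor count; shift the two curvature columns positive first
   (x − min + 0.001, so the minimum maps to ln 0.001); drop rows beyond
   median ± 8·MAD in any column (dropped rows are always reported with a
   reason: area_missing, area_zero, outlier, missing_sa); standardize;
   PCA (loadings reported as variable–PC correlations, each PC's sign
   fixed so its largest loading is positive); Ward linkage on all PC
   scores, tree cut at k = 5. Per-cluster boxplot statistics are in
   global-SD units, so a cluster mean |z| > 2 flags an outlier cluster.
   An optional k-means consolidation pass exists but is off by default.

## The synthetic generator

The generator emulates the study conditions so the full pipeline can be
validated end to end.

**Shape.** A cross-section swept along the anteroposterior axis with an
elliptic taper (`f(t) = (1−|2t−1|^p)^{1/p}`, p = 2, so longitudinal
curvature is positive everywhere). Rounded-polygon sections use a
smooth-max of the face half-planes (the superellipse construction for
the tetragonal class): sides genuinely flat, corner radius set by
`corner_rounding` (trunk default 0.30). The corners morph to an almost
oval section (`head_rounding` 0.85) over the anterior transition —
lateral keels fade toward the head, as in real cross-sections. Bounding
extents match (length, height, width) to within 2%.

**Tessellation.** A graded, staggered near-hexagonal lattice in (sweep,
perimeter) coordinates seeds the Voronoi sites: density ×2.2 in the
head (anterior 35%), ×2.5 on the corner arcs (top quartile of
cross-section curvature; ×1.6 more on the sharpest decile), and a
Gaussian bump (×5) around each opening; in-row jitter σ = 0.30 of the
spacing; three Lloyd iterations with Euclidean (geodesic-approximating)
distance on face centroids; region connectivity enforced afterwards.
Openings are anatomical: mouth and caudal gap at the tapered apexes,
paired eyes and pectoral openings anterior; the scute containing each
opening point is relabeled 0.

**Planted types.** Each scute is typed by the zone of its faces: sharp
edge / moderate edge (corner-curvature tiers along the trunk), abdomen,
head, or opening-adjacent (opening rims, their densified vicinity, and
the apex belts). Shell thickness is base × a type multiplier —
1.7×`edge_thickness_factor` (sharp), `edge_thickness_factor` (moderate,
default 1.8), 1.0 (abdomen and head), 2.4 (opening-adjacent) — with 3%
lognormal per-scute jitter. Without planted types, `voxelize` applies
the generic rule: ×`edge_thickness_factor` where the local
mean-curvature proxy exceeds its 75th percentile.

**Voxelization.** Faces are densely point-sampled (half-voxel spacing),
splatted into a grid, the interior filled, and the shell taken as solid
voxels within the local thickness of the nearest surface sample
(condition calibrated on an analytic sphere shell to ~1% volume error).
Opening faces carve background gaps. Voxel size must resolve the base
thickness with ≥ 2 voxels. Identical spec + seed reproduces the label
field bit-exactly.

**Batches.** `simulate_batch` draws 13 specimens spanning a four-fold
length range; scute counts are drawn uniformly so measured counts land
in the interspecific range 398–535 (six scutes become openings);
carapace proportions follow the geometry class (elliptic relatively high
and narrow, tetragonal low and wide) with 5% lognormal jitter; voxel
size and shell thickness scale with length, keeping relative resolution
constant — the same convention a scan protocol follows.

## What the synthetic data shows, and what it does not

Passing tests on synthetic batches demonstrate that the measurement and
statistics pipeline recovers what was planted: isometric exponents
within their CIs across a four-fold size range, size-independent scute
counts, a curvature threshold that separates the planted edge and flat
regions, and (largely) the five planted scute types under PCA + Ward
clustering. They do not certify segmentation quality on real microCT
data, nor the biological realism of the planted covariances.

Known divergences from real carapaces:

* The tessellation retains more four-valent junctions than real
  carapaces (mean RAG degree ≈ 5.82 versus the trivalent ideal
  6 − 12/n ≈ 5.97), so the pentagon share runs ~2 percentage points
  above the upper end observed in real specimens (batch median ≈ 24%
  versus ≤ 22%); hexagons remain modal everywhere, flanked by pentagons
  and heptagons.
* Opening-adjacent scutes sit partly on the curved apex belts, so their
  normalized CGS is intermediate between edge and flat types; in real
  carapaces the scutes around openings lie in flat regions. The
  edge-versus-flat curvature ordering (both edge types above abdomen and
  head) is robust.
* Planted-type recovery by Ward at k = 5 has realization noise: the
  adjusted Rand index against the generator's labels is ≈ 0.68–0.73
  across batch seeds. The binding confusions are the two adjacent edge
  curvature tiers and the internal spread of the opening-adjacent type.
* Plane-based areas and SA are measured on the dual surface through
  mid-shell scute centers, so SA sits below the outer surface area by a
  shell-geometry factor; all scaling analyses are unaffected (the bias
  is scale-invariant).

## Numerical choices and degenerate inputs

* MISSING_FLAG is exactly −1000, matching the deposited-data convention.
* Thickness/width of planar or linear voxel sets fall back to the voxel
  size floor, with a warning.
* Degenerate triangles contribute zero area with a warning; empty
  meshes, empty label fields, collinear center clouds, unknown ids,
  non-positive regression inputs and k > n all raise with a message
  naming the offender.
* The interaction test reports NaN (with a warning) when the stacked
  regression is degenerate (zero residual variance).
* The outlier rule (median ± 8·MAD per transformed column) is
  deliberately permissive — it removes only pathological scutes (the
  analog of extreme horn scutes), and every removal is reported.
* Determinism: every stochastic step takes an explicit seed; a pipeline
  rerun with the same config writes byte-identical CSVs.

## Problem sizes

The default study batch is 13 specimens of 398–535 scutes each
(~5900 scutes), voxelized at ~143 voxels per body length (grids around
150×90×80 at the small end). One specimen synthesizes and measures in
about 10 s on one CPU; the full batch plus all statistics takes a few
minutes. The tessellation mesh (160×128 sweep grid, ~41k faces) keeps
~80 faces per scute, enough for clean region boundaries.
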
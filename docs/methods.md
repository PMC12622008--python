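# Methods

This note documents the models, rules, parameters, and numerical choices
behind `tlsniche`, and what the synthetic benchmark does and does not show.

## Coordinate and distance conventions

All geometry is 2D Euclidean in micrometres on cell centroids, with the
image convention (x rightward, y downward, origin top-left). Distances to a
polygon are point-to-boundary distances, zero for any point inside or on the
boundary. All distance axes are therefore nonnegative and 1-Lipschitz in
cell position, a property the test suite checks by perturbation.

## TLS polygons

TLS-zone cells are grouped into instances by DBSCAN with radius `group_eps`
(default 50 μm, min 3 cells): TLS are spatially compact and well separated,
so a density radius well below the typical inter-TLS spacing delimits them
cleanly. Each group gets an alpha-shape concave hull: the union of Delaunay
triangles with circumradius ≤ `concavity` (default 150 μm), holes filled
(a TLS is a solid structure), largest component kept, with the convex hull
as the `concavity → ∞` limit and as fallback when no triangle qualifies.
Hulls with area below `min_area` (default 5,000 μm², roughly a 40 μm-radius
aggregate) are discarded so that sparse clouds of TLS-typed cells do not
count as mature structures. Enlarging `min_area` can only remove polygons
(monotone filter). Polygon ids are assigned in centroid (x, y) order for
determinism.

The polygon centroid is the area centroid; for concave shapes it may lie
outside the ring, in which case the radial partition still uses it (scaled
distances remain well defined).

## Distance axes

- `d_TLS`: minimum distance to any mature TLS polygon; exactly 0 inside.
  With no polygons the axis is undefined and flagged NaN rather than
  infinite.
- `d_bronchi`: mean distance to the k = 10 nearest bronchi-zone cells;
  bronchi-zone members get 0. Fewer than k zone cells is an error, not a
  silent fallback, because the k-nearest mean is then undefined as
  specified.
- Axis profiles exclude cells beyond 450 μm, where the tissue context no
  longer relates to the anchoring structure.

## Radial partition of a TLS

Inside cells (boundary inclusive) get the centroid distance r, min–max
scaled within their TLS to r_scaled ∈ [0, 1]; r_scaled ≤ 0.5 is **core**,
otherwise **outer**. The split is a threshold on the scaled distance itself
(default), because the quantity named by the classification is the scaled
radius; a per-TLS count-median split (`split_mode="count"`) is available
for analyses that want equal cell numbers per half. A TLS whose inside
cells are all equidistant from the centroid (for example a single cell)
gets r_scaled = 0 and is core. Cells outside every polygon whose edge
distance lies in (0, 50 μm] form the **surrounding** ring. Core and outer
partition the inside set exactly; the ring is disjoint from both. When
polygons overlap a cell is attributed to the lowest-id covering polygon
(overlap does not occur with the default grouping).

## Expression normalization

Counts are depth-normalized per cell to the median total count;
gradient profiles use the log1p transform of that (the conventional scale
for smoothed expression heatmaps). Region means and marker fold changes
use the *linear* normalized values: ratios of linear means reflect
count-scale arithmetic directly, whereas ratios of log-means compress true
fold changes (a 3-fold difference in means can shrink below 2-fold on the
log scale). The choice is recorded in the output metadata.

## Convolved gradients

Cells within the 450 μm cut are ordered by axis value (ties broken by cell
id for determinism) and each gene is smoothed with a centered moving
average over `window` = 50 cells, the window shrinking at the edges.
Window 1 is the identity; smoothing commutes with adding a constant. Fifty
cells is a standard smoothing span for convolved single-cell heatmaps:
wide enough to suppress Poisson noise at the panel's expression levels,
narrow relative to the thousands of cells on an axis.

## Weighted kernel density

The expression-weighted density on the (d_TLS, d_bronchi) plane is a
product-Gaussian KDE with bandwidth in μm (default 25), per-cell weights
normalized to sum to 1, evaluated on a regular grid padded by 3 bandwidths
and normalized to integrate to 1 (so it is invariant to rescaling all
weights). Inputs larger than 50,000 cells are uniformly subsampled with
the run seed.

## Region rules

- **T/B/P**: T iff d_TLS ≤ 50 μm; else B iff d_bronchi ≤ 50 μm; else P iff
  both distances ≤ 450 μm; else none. T precedes B because TLS can abut
  bronchi and the TLS context dominates. The 50 μm thresholds are package
  defaults (about two to three cell diameters).
- **Microscopy categories**: TLS (< 50 μm), else bronchi (< 50 μm), else
  vessel (< 100 μm from a vessel, ≥ 50 μm from TLS), else alveolar
  (> 50 μm from all three), else other. As printed, the vessel and alveolar
  clauses overlap for cells 50–100 μm from a vessel and far from everything
  else; the vessel clause takes priority, which keeps the rule a strict
  priority cascade.

Both rules are pure, total on defined distances, and monotone in their
thresholds (raising t_max never removes a T label).

## Marker testing

Zone-vs-rest, two-sided Mann–Whitney U on depth-normalized expression,
restricted to genes detected (count > 0) in at least 5 % of cells of both
compared groups, Benjamini–Hochberg across all tests, pass iff adjusted
p < 0.05 and |log₂FC| > 1 with pseudocount 1 on the normalized means.
Zones with fewer than 2 cells are excluded with a warning. Under label
permutation the pass fraction is controlled at the nominal level (the
fold-change gate makes it conservative); a planted 8-fold marker at
n = 200 per group is detected with power ≥ 0.9.

## Interaction analysis

The spatial graph is a union-symmetrized k-nearest-neighbor graph
(default k = 6, a typical contact number for packed epithelium-like
tissue); fixed-radius and Delaunay constructions are available. Per zone,
edges with both endpoints in the zone are tallied by the endpoint type
pair; the raw matrix is symmetric and retained alongside an optional
row-max scaling.

The ligand–receptor score deliberately replaces mass-action communication
models with a transparent range-gated product: the trimmed mean (trim 0.1
per tail) of ligand expression over sender-type cells lying within 50 μm of
at least one receiver cell, times the trimmed mean of receptor expression
over the receivers. The score is zero with no sender in range, invariant
to receiver ordering, and monotone nondecreasing in the range. A
`contact_range` parameter (10 μm) is accepted for interface parity with
communication tools but does not enter the score, since the simplified
model has no secreted/contact distinction. Incoming signals are min–max
scaled per pathway across receiver categories; constant rows map to zero.

## Demultiplexing and QC

A droplet is assigned to its top hashtag iff that count is ≥ 10 and
strictly more than double the second-highest; externally flagged doublets
are excluded; everything else is unassigned. Exactly double fails the rule.
Columns are processed in sorted hashtag order so the result is invariant to
input column order, with ties broken toward the lexicographically lowest
hashtag. Doublet detection itself is an external input; a naive fallback
(two hashtags each ≥ 10 and within 2× of each other) is provided off by
default and labeled a stand-in.

CITE-seq QC keeps a droplet iff RNA counts ≥ 500, mitochondrial fraction
≤ 10 %, surface-tag counts ≥ 500, and fewer than two positive isotype
controls — the exclusions are strict readings of "fewer than 500" and
"over 10 %", so boundary droplets pass. Spatial QC keeps cells with ≥ 10
transcripts. Exclusion reasons are logged per cell.

## Zoning stand-in

Full spatial-neighborhood models (latent-representation clustering with
neighborhood aggregation) are out of scope; zone labels are an input to
everything downstream. The provided stand-in computes each cell's
k-nearest-neighbor cell-type composition (self plus k = 10 neighbors, rows
summing to 1) and fits a diagonal-covariance Gaussian mixture with a fixed
seed, renaming clusters by majority ground-truth zone when truth is
available. On synthetic tissue with well-separated structures it recovers
the true zones with adjusted Rand index ≈ 0.82–0.86. The capsule is then
split off by rule: mean distance to the 5 nearest mesothelial cells
≤ 100 μm (inclusive) ⇒ capsule. The rule is idempotent.

## Synthetic tissue generator

The generator emulates a lung section: TLS as discs (radius ~N(150, 20²)
μm) dense in B cells and progenitor CD4 T cells; bronchi as 30 μm
epithelial annuli around a 100 μm empty lumen with some Th2 cells; vessels
as endothelial discs; a 60 μm mesothelium-lined capsule strip along the
bottom edge; parenchyma elsewhere. Structures are placed by rejection
sampling with a margin and a fixed attempt bound; an unplaceable structure
raises an error naming it. Cell numbers per structure are Poisson at
configurable densities (TLS 60, bronchi 40, parenchyma 8 cells per
10⁴ μm² by default, reflecting the density contrast between lymphoid
aggregates and alveolar tissue).

Expression follows a distance-decay model: for CD4 T cells, progenitor
genes have expected count a·exp(−d_TLS/λ) + b and effector genes
a·exp(−d_bronchus/λ) + b with defaults a = 20, λ = 100 μm, b = 1.
The exponential form is a simulation choice — the observation being
emulated is only that the gradients are monotone — and is recorded in the
ground truth so recovery tests can fit it. Ligand-class genes are expressed
by antigen-presenting cells (macrophages, cDC2) and decay with distance to
the nearest TLS *center*, putting peak ligand availability in the TLS core;
the receptor is constant on CD4 T cells. Structural genes mark their own
compartment; housekeeping genes are uniform. Counts are negative-binomial
with configurable dispersion θ (variance μ + μ²/θ), Poisson in the θ → ∞
default; spatial count data are often overdispersed, so θ is exposed.
`gradient_recovery_config()` provides the canonical benchmark condition: a
2 × 2 mm CD4-rich field yielding ≈ 5,000 CD4 T cells, on which nonlinear
least squares recovers λ within a few percent and the convolved gradient
profiles are monotone with |Spearman ρ| > 0.95.

What the generator does **not** emulate: transcript-level spot noise,
segmentation errors, cell-shape anisotropy, 3D structure, batch effects, or
realistic panel sizes (14 genes vs hundreds). Tests passing on it show the
geometry, rules, and statistics are implemented correctly and recover known
truth under clean conditions; they do not certify performance on real
sections with imperfect segmentation and diffuse structure boundaries.

## Determinism

Every stochastic step (placement, counts, subsampling, mixture fitting)
takes an explicit seed; the full pipeline run twice with one configuration
produces byte-identical outputs, and every run log records the resolved
configuration and its hash.

## Problem sizes

The bundled benchmark and test conditions use fields of 1.5–3 mm with
~9,000–12,000 cells, 20 random 100–500-cell instances per brute-force
geometry comparison, 20 label permutations for calibration, and 20
replicates for power; these desk-scale sizes are the package's reference
conditions and complete in well under a minute each.

## Known limitations

- The zoning stand-in clusters on composition only; it will not separate
  zones distinguished by expression but not by cell-type mixture.
- The LR score is not a probability and is not calibrated across pathways;
  only orderings and min–max-scaled comparisons are meaningful.
- Concave hulls depend on the `concavity` length; very sparse TLS groups
  can fall back to convex hulls.
- The T/B/P thresholds (50 μm) and the interaction graph rule (knn, k = 6)
  are package defaults for quantities the underlying study leaves
  unstated; both are configurable.
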
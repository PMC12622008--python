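# tlsniche

Spatial niche analysis of tertiary lymphoid structures (TLS) in tissue
sections, built for imaging-based spatial transcriptomics of inflamed lung.

In allergen-challenged lung, stem-like (TCF1⁺/Tcf7-high) CD4 T cells
concentrate inside TLS — dense ectopic aggregates of B cells and CD4 T cells
— while differentiated Th2 effectors (GATA3⁺, ST2⁺, CXCR6⁺) occupy the
airways and parenchyma. Resolving that spatial bifurcation requires anchoring
every segmented cell to the tissue's structures: how far is it from the
nearest mature TLS, from the bronchial epithelium, and where does it sit
within its TLS? `tlsniche` implements that analysis as a tested, reusable
pipeline:

- **TLS polygon construction** — density-based grouping of TLS-zone cells
  (DBSCAN, radius `group_eps`), an alpha-shape concave hull per group
  (characteristic length `concavity`; convex hull in the limit
  `concavity → ∞`), and a minimum-area filter that keeps only mature TLS.
- **Distance axes** — `d_TLS`: Euclidean distance to the closest TLS polygon
  (0 inside or on the boundary); `d_bronchi`: mean distance to the 10 nearest
  bronchi-zone cells (0 for members); cells beyond 450 μm are excluded from
  axis profiles.
- **Radial partition** — per TLS, the centroid distance *r* of inside cells
  is min–max scaled; cells with scaled radius ≤ 0.5 form the **core**, the
  rest the **outer** region, and cells within 50 μm outside the polygon edge
  the **surrounding ring**.
- **Expression gradients** — centered moving-average ("convolved") expression
  for cells ordered along an axis, expression-weighted 2D Gaussian KDE on the
  (d_TLS, d_bronchi) plane, T/B/P region assignment (close to TLS / close to
  bronchi / parenchyma), and zone-vs-rest marker tests (Mann–Whitney U,
  Benjamini–Hochberg, pass iff adjusted p < 0.05 and |log₂FC| > 1, genes
  detected in ≥ 5 % of both groups).
- **Interactions** — per-zone cell-type × cell-type neighbor edge counts on a
  spatial graph, and a range-gated ligand–receptor score
  `TM_trim(ligand | senders within 50 μm of a receiver) ×
  TM_trim(receptor | receivers)` with a 0.1 trimmed mean.
- **Zoning rules** — external zone labels, a k-NN composition-clustering
  stand-in, and the capsule rule (mean distance to the 5 nearest mesothelial
  cells ≤ 100 μm ⇒ capsule).
- **CITE-seq preprocessing** — hashtag demultiplexing (top hashtag ≥ 10
  counts and strictly more than double the runner-up; doublets excluded) and
  droplet QC (≥ 500 RNA counts, ≤ 10 % mitochondrial, ≥ 500 surface-tag
  counts, fewer than two positive isotype controls); spatial QC drops cells
  with < 10 transcripts.
- **Synthetic tissue generator** — a lung-like field of TLS discs, bronchial
  annuli, vessels, a mesothelial capsule and parenchyma with exponential
  expression gradients (expected counts `a·exp(−d/λ) + b`) and known ground
  truth, so every stage is verifiable without any external data.

## Worked example

```python
from tlsniche import SimConfig, generate_tissue
from tlsniche.geometry import (build_tls_polygons, distance_to_tls,
                               distance_to_zone_cells, radial_partition)
from tlsniche.axes import (normalize_expression, assign_tbp,
                           region_mean_expression)

cfg = SimConfig(seed=0)                      # 3×3 mm field, 3 TLS, 3 bronchi
cells, expression, truth = generate_tissue(cfg)

tls_cells = cells[cells["true_zone"] == "TLS"]
polygons = build_tls_polygons(tls_cells, group_eps=50, concavity=150,
                              min_area=5000)
d_tls = distance_to_tls(cells, polygons)["d_tls"]
d_bronchi = distance_to_zone_cells(cells, cells["true_zone"],
                                   zone="bronchi", k=10)
radial = radial_partition(cells, polygons, ring_width=50, split=0.5)

tbp = assign_tbp(d_tls, d_bronchi, t_max=50, b_max=50)
cd4 = cells["cell_type"].str.startswith("CD4")
linear = normalize_expression(expression, log=False)
print(region_mean_expression(linear.loc[cells.index[cd4]], tbp[cd4])
      [["Tcf7", "Gata3"]].round(2))
```

Output:

```
9164 cells, 14 genes
TLS 0: area 67,926 um^2, centroid (216, 2282)
TLS 1: area 78,451 um^2, centroid (2104, 1584)
TLS 2: area 63,971 um^2, centroid (2601, 1748)
{'none': 7650, 'outer': 993, 'core': 397, 'surrounding': 124}
gene    Tcf7  Gata3
region
B       0.42   5.52
P       1.78   2.39
T       5.61   0.37
```

All three simulated TLS are recovered as mature polygons; their interiors
split into core (397 cells) and outer (993) regions with a 124-cell
surrounding ring. CD4 T cells near TLS (region T) express the stem marker
*Tcf7* ~3-fold above parenchyma (5.61 vs 1.78 depth-normalized counts) and
almost no *Gata3*, while cells near bronchi (region B) show the mirror-image
Th2 profile — the spatial bifurcation the pipeline is designed to measure.

A `tlsniche` command-line interface exposes the stages as subcommands
(`simulate`, `demux`, `qc`, `zones`, `geometry`, `axes`, `interactions`,
`run-all`), each accepting `--config` and `--seed`.

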
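"""Analysis along structure-anchored distance axes.

Given per-cell distances to TLS and bronchi (and optionally vessels), this
module computes convolved (moving-average) expression gradients for cells
ordered along an axis, expression-weighted 2D kernel densities on the
(d_tls, d_bronchi) plane, T/B/P region assignment (close to TLS, close to
bronchi, parenchyma), per-region mean expression, rank-sum zone marker tests
with Benjamini-Hochberg correction, and the microscopy distance
categorization (TLS < 50 μm, bronchi < 50 μm, vessel < 100 μm while > 50 μm
from TLS, alveolar > 50 μm from all three).

Expression used for gradients and region means is, by pipeline convention,
counts normalized per cell to the median total count and log1p-transformed
(:func:`normalize_expression`); the functions themselves accept any
per-cell values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests


def normalize_expression(expression: ad.AnnData, log: bool = True) -> pd.DataFrame:
    """Median-total depth normalization, optionally log1p-transformed.

    Each cell's counts are scaled to sum to the median total count across
    cells (cells with zero counts are left at zero); with ``log=True`` the
    result is log1p-transformed.  Returns a dense cells × genes DataFrame.
    """
    X = expression.X
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    totals = dense.sum(axis=1, dtype=float)
    median = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scale = np.divide(median, totals, out=np.zeros_like(totals), where=totals > 0)
    normalized = dense * scale[:, None]
    return pd.DataFrame(
        np.log1p(normalized) if log else normalized,
        index=expression.obs_names,
        columns=expression.var_names,
    )


@dataclass
class GradientProfile:
    """Convolved expression along a distance axis."""

    axis: str
    cell_ids: pd.Index  # ordered by ascending axis value
    axis_values: np.ndarray
    profile: pd.DataFrame  # cells (ordered) × genes, smoothed
    window: int


def convolve_along_axis(
    expression: pd.DataFrame,
    axis_values: pd.Series,
    genes: list[str] | None = None,
    window: int = 50,
    max_dist: float | None = 450.0,
    axis_name: str = "d_tls",
) -> GradientProfile:
    """Moving-average expression for cells ordered along a distance axis.

    Cells with axis value above ``max_dist`` (450 μm by default; pass None
    for axes like the scaled radial distance that need no cut) are excluded.
    The rest are sorted ascending by axis value, ties broken by cell id, and
    each gene is smoothed by a centered moving average over ``window`` cells
    with the window shrinking at the edges.  ``window=1`` returns the raw
    ordered values.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    axis_values = axis_values.reindex(expression.index)
    keep = axis_values.notna()
    if max_dist is not None:
        keep &= axis_values <= max_dist
    if not keep.any():
        raise ValueError(
            f"no cells with {axis_name} <= {max_dist}: nothing to profile"
        )
    sub = axis_values[keep]
    order = (
        pd.DataFrame({"v": sub, "cid": sub.index})
        .sort_values(["v", "cid"], kind="mergesort")
        .index
    )
    cols = list(genes) if genes is not None else list(expression.columns)
    ordered = expression.loc[order, cols]
    smoothed = ordered.rolling(window, center=True, min_periods=1).mean()
    return GradientProfile(
        axis=axis_name,
        cell_ids=ordered.index,
        axis_values=sub.loc[order].to_numpy(),
        profile=smoothed,
        window=window,
    )


def weighted_kde_2d(
    d_tls: pd.Series,
    d_bronchi: pd.Series,
    weights: pd.Series,
    bandwidth: float = 25.0,
    grid_size: int = 128,
    max_cells: int = 50000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expression-weighted Gaussian KDE on the (d_tls, d_bronchi) plane.

    Per-cell weights (e.g. a gene's expression) are normalized to sum to 1;
    the returned density grid integrates to 1.  When more than ``max_cells``
    cells are supplied a uniform subsample (with ``seed``) is used.

    Returns ``(x_grid, y_grid, density)`` where density[i, j] corresponds to
    ``(x_grid[j], y_grid[i])``.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    df = pd.DataFrame({"x": d_tls, "y": d_bronchi, "w": weights}).dropna()
    if (df["w"] < 0).any():
        raise ValueError("weights must be nonnegative")
    if df["w"].sum() <= 0:
        raise ValueError("all-zero weights: nothing to weight the density by")
    if len(df) > max_cells:
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.choice(len(df), size=max_cells, replace=False)]
        if df["w"].sum() <= 0:
            raise ValueError("subsample carries zero total weight")
    w = df["w"].to_numpy() / df["w"].sum()
    pad = 3 * bandwidth
    gx = np.linspace(df["x"].min() - pad, df["x"].max() + pad, grid_size)
    gy = np.linspace(df["y"].min() - pad, df["y"].max() + pad, grid_size)
    # separable Gaussian kernels, (grid, cells)
    kx = np.exp(-0.5 * ((gx[:, None] - df["x"].to_numpy()[None, :]) / bandwidth) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - df["y"].to_numpy()[None, :]) / bandwidth) ** 2)
    density = ky @ (w[:, None] * kx.T)  # (grid_y, grid_x)
    dx = gx[1] - gx[0] if grid_size > 1 else 1.0
    dy = gy[1] - gy[0] if grid_size > 1 else 1.0
    total = density.sum() * dx * dy
    density /= total
    return gx, gy, density


def assign_tbp(
    d_tls: pd.Series,
    d_bronchi: pd.Series,
    t_max: float = 50.0,
    b_max: float = 50.0,
    max_dist: float = 450.0,
) -> pd.Series:
    """Label cells T (close to TLS), B (close to bronchi) or P (parenchyma).

    Priority is T over B (TLS can abut bronchi): T iff d_tls <= t_max, else
    B iff d_bronchi <= b_max, else P iff both distances are within
    ``max_dist``, else none.
    """
    d_tls, d_bronchi = d_tls.align(d_bronchi, join="inner")
    label = pd.Series("none", index=d_tls.index, dtype=object, name="tbp")
    p = (d_tls <= max_dist) & (d_bronchi <= max_dist)
    label[p] = "P"
    label[d_bronchi <= b_max] = "B"
    label[d_tls <= t_max] = "T"
    label[d_tls.isna() | d_bronchi.isna()] = "none"
    return label


def categorize_imaging(
    d_tls: pd.Series, d_bronchi: pd.Series, d_vessel: pd.Series
) -> pd.Series:
    """Microscopy distance categorization of cells.

    Priority order: TLS (< 50 μm), bronchi (< 50 μm), vessel (< 100 μm and
    at least 50 μm from TLS), alveolar (> 50 μm from TLS, bronchi and
    vessels); anything left is ``other``.  As printed, the vessel and
    alveolar clauses overlap for cells 50-100 μm from a vessel but far from
    everything else; the vessel clause takes priority here.
    """
    idx = d_tls.index
    d_b = d_bronchi.reindex(idx)
    d_v = d_vessel.reindex(idx)
    label = pd.Series("other", index=idx, dtype=object, name="imaging")
    alveolar = (d_tls > 50) & (d_b > 50) & (d_v > 50)
    label[alveolar] = "alveolar"
    label[(d_v < 100) & (d_tls >= 50)] = "vessel"
    label[d_b < 50] = "bronchi"
    label[d_tls < 50] = "TLS"
    label[d_tls.isna() | d_b.isna() | d_v.isna()] = "other"
    return label


def region_mean_expression(
    expression: pd.DataFrame,
    labels: pd.Series,
    genes: list[str] | None = None,
    drop: tuple[str, ...] = ("none",),
) -> pd.DataFrame:
    """Arithmetic mean expression per region label (region × gene).

    Regions with no cells are omitted with a warning; labels in ``drop``
    are never reported.
    """
    labels = labels.reindex(expression.index)
    cols = list(genes) if genes is not None else list(expression.columns)
    used = labels[~labels.isin(drop) & labels.notna()]
    if used.empty:
        warnings.warn("no cells in any reportable region")
        return pd.DataFrame(columns=cols)
    means = expression.loc[used.index, cols].groupby(used).mean()
    means.index.name = "region"
    return means


def zone_marker_test(
    expression: ad.AnnData,
    zones: pd.Series,
    min_frac: float = 0.05,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Zone-vs-rest marker genes by rank-sum test with BH correction.

    For each zone with at least 2 cells, genes detected (count > 0) in at
    least ``min_frac`` of cells of *both* compared groups (the zone and the
    rest) are tested with a two-sided Mann-Whitney U on depth-normalized
    (linear) expression.  log2 fold change uses the ratio of the normalized
    group means with a pseudocount of 1.  Benjamini-Hochberg adjustment is applied
    across all tests; a gene passes iff adjusted p < ``alpha`` and
    |log2FC| > ``lfc_min``.

    Returns a frame with columns gene, zone, log2fc, pval, padj, passed.
    """
    zones = zones.reindex(expression.obs_names)
    norm = normalize_expression(expression, log=False)
    X = expression.X
    detected = (X.toarray() if sparse.issparse(X) else np.asarray(X)) > 0

    zone_names = [z for z in sorted(zones.dropna().unique())]
    counts = zones.value_counts()
    usable = [z for z in zone_names if counts.get(z, 0) >= 2]
    for z in set(zone_names) - set(usable):
        warnings.warn(f"zone {z!r} has fewer than 2 cells and is excluded")
    if len(usable) < 2:
        raise ValueError("marker testing needs at least 2 zones with >= 2 cells")

    rows = []
    values = norm.to_numpy()
    gene_names = list(norm.columns)
    for z in usable:
        in_zone = (zones == z).to_numpy()
        rest = ~in_zone & zones.notna().to_numpy() & zones.isin(usable).to_numpy()
        if rest.sum() < 2:
            warnings.warn(f"rest group for zone {z!r} has fewer than 2 cells; skipped")
            continue
        frac_zone = detected[in_zone].mean(axis=0)
        frac_rest = detected[rest].mean(axis=0)
        testable = (frac_zone >= min_frac) & (frac_rest >= min_frac)
        for j in np.flatnonzero(testable):
            a_vals = values[in_zone, j]
            b_vals = values[rest, j]
            if np.all(a_vals == a_vals[0]) and np.all(b_vals == a_vals[0]):
                p = 1.0
            else:
                p = stats.mannwhitneyu(a_vals, b_vals, alternative="two-sided").pvalue
            lfc = float(np.log2((a_vals.mean() + 1.0) / (b_vals.mean() + 1.0)))
            rows.append((gene_names[j], z, lfc, float(p)))

    table = pd.DataFrame(rows, columns=["gene", "zone", "log2fc", "pval"])
    if table.empty:
        table["padj"] = []
        table["passed"] = []
        return table
    table["padj"] = multipletests(table["pval"], method="fdr_bh")[1]
    table["passed"] = (table["padj"] < alpha) & (table["log2fc"].abs() > lfc_min)
    return table
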
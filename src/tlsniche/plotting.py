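"""Static plots: tissue maps with TLS polygons and axis-plane densities."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .geometry import TLSPolygon


def plot_tissue(
    cells: pd.DataFrame,
    zones: pd.Series | None = None,
    polygons: list[TLSPolygon] | None = None,
    path: str | Path | None = None,
    point_size: float = 2.0,
):
    """Scatter the tissue colored by zone (or cell type), with TLS outlines.

    The y axis is inverted to match the image convention.  Returns the
    figure; saves to ``path`` when given.
    """
    fig, ax = plt.subplots(figsize=(7, 7))
    labels = zones.reindex(cells.index) if zones is not None else cells["cell_type"]
    for name in sorted(labels.dropna().unique()):
        sub = cells[labels == name]
        ax.scatter(sub["x_um"], sub["y_um"], s=point_size, label=str(name))
    for p in polygons or []:
        ring = np.asarray(p.exterior_coords)
        ax.plot(ring[:, 0], ring[:, 1], color="black", lw=1.2)
        ax.annotate(str(p.tls_id), p.centroid, ha="center", fontsize=8)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.legend(markerscale=4, fontsize=7, loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_axis_density(
    gx: np.ndarray,
    gy: np.ndarray,
    density: np.ndarray,
    path: str | Path | None = None,
    title: str = "",
):
    """Heatmap of an expression-weighted density on the (d_TLS, d_bronchi) plane."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(gx, gy, density, shading="auto", cmap="magma")
    fig.colorbar(im, ax=ax, label="density")
    ax.set_xlabel("distance to TLS (μm)")
    ax.set_ylabel("distance to bronchi (μm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
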
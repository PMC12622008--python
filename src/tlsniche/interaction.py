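"""Per-zone neighbor interaction matrices and range-gated ligand-receptor
scores.

A spatial neighbor graph (symmetrized knn, fixed-radius, or Delaunay) is
built on cell centroids; per zone, edges incident to a focal cell type are
tallied by partner type into a type × type interaction matrix (optionally
row-scaled to a maximum of 1, with raw counts always retained).  Spatial
ligand-receptor communication is scored with a deliberately transparent
stand-in for mass-action communication models: the trimmed mean of ligand
expression over sender-type cells that lie within ``range_um`` of at least
one receiver cell, times the trimmed mean of receptor expression over the
receiver cells, trimming a fraction (default 0.1) from each tail.  A
``contact_range`` parameter is accepted for interface parity with
communication tools but does not enter the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import trim_mean


def build_spatial_graph(
    cells: pd.DataFrame,
    method: str = "knn",
    k: int = 6,
    radius: float = 30.0,
) -> nx.Graph:
    """Undirected spatial neighbor graph over cell centroids.

    ``knn`` connects each cell to its ``k`` nearest neighbors and
    symmetrizes by union; ``radius`` connects all pairs within ``radius``
    μm; ``delaunay`` uses the Delaunay triangulation edges.  Nodes are cell
    ids; no self-edges.  Cells are processed in cell-id order so ties in
    neighbor distance resolve deterministically.
    """
    if len(cells) < 2:
        raise ValueError(f"need at least 2 cells to build a graph, got {len(cells)}")
    cells = cells.sort_index()
    ids = cells.index.to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if method == "knn":
        kk = min(k, len(cells) - 1)
        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=kk + 1)
        idx = np.atleast_2d(idx)
        for i in range(len(ids)):
            for j in idx[i, 1:]:
                g.add_edge(ids[i], ids[j])
    elif method == "radius":
        tree = cKDTree(xy)
        for i, j in sorted(tree.query_pairs(radius)):
            g.add_edge(ids[i], ids[j])
    elif method == "delaunay":
        if len(cells) < 3:
            raise ValueError("delaunay graph needs at least 3 cells")
        tri = Delaunay(xy)
        for simplex in tri.simplices:
            for a in range(3):
                g.add_edge(ids[simplex[a]], ids[simplex[(a + 1) % 3]])
    else:
        raise ValueError(f"unknown graph method {method!r}")
    return g


def interaction_matrix(
    graph: nx.Graph,
    cell_types: pd.Series,
    zones: pd.Series,
    focal_type: str,
    row_scale: bool = True,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-zone cell-type × cell-type neighbor edge counts.

    Only edges whose two endpoints both lie in the zone are counted; each
    edge increments both (type_u, type_v) and (type_v, type_u), so the raw
    matrix is symmetric (a same-type edge adds 2 on the diagonal).  Zones
    without any focal-type cell get a zero focal row with a warning.

    Returns ``{zone: {"raw": counts, "scaled": row-scaled}}``; scaling
    divides each row by its maximum (zero rows stay zero) and is only
    attached when ``row_scale`` is true.
    """
    types = cell_types.astype(str)
    zone_s = zones.astype(str)
    all_types = sorted(types.unique())
    result: dict[str, dict[str, pd.DataFrame]] = {}
    for zone in sorted(zone_s.dropna().unique()):
        members = set(zone_s.index[zone_s == zone])
        mat = pd.DataFrame(0, index=all_types, columns=all_types, dtype=float)
        for u, v in graph.edges:
            if u in members and v in members:
                tu, tv = types[u], types[v]
                mat.loc[tu, tv] += 1
                mat.loc[tv, tu] += 1
        if focal_type in types[types.index.isin(members)].values:
            pass
        else:
            warnings.warn(f"zone {zone!r} contains no {focal_type!r} cells (zero row)")
        out = {"raw": mat}
        if row_scale:
            maxima = mat.max(axis=1)
            scaled = mat.div(maxima.where(maxima > 0, 1.0), axis=0)
            out["scaled"] = scaled
        result[zone] = out
    return result


@dataclass
class LRScore:
    """Range-gated ligand-receptor communication score."""

    ligand: str
    receptor: str
    sender_type: str
    receiver_category: str
    score: float
    n_sender_in_range: int
    n_receiver: int


def lr_spatial_score(
    expression: pd.DataFrame,
    cells: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender_type: str,
    receiver_ids: pd.Index | list,
    receiver_category: str = "",
    range_um: float = 50.0,
    trim: float = 0.1,
    contact_range: float | None = None,  # interface parity; unused
) -> LRScore:
    """Score communication from a sender cell type to a receiver cell set.

    score = TM(ligand over sender-type cells within ``range_um`` of >= 1
    receiver) × TM(receptor over receivers), with TM the trimmed mean
    discarding the ``trim`` fraction at each tail.  Zero when no sender is
    in range.  Invariant to receiver ordering and monotone nondecreasing in
    ``range_um``.
    """
    del contact_range
    for gene in (ligand, receptor):
        if gene not in expression.columns:
            raise KeyError(f"gene {gene!r} not present in the expression matrix")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    receiver_ids = pd.Index(receiver_ids).unique()
    receivers = cells.loc[cells.index.intersection(receiver_ids)]
    senders = cells[cells["cell_type"] == sender_type]
    if len(receivers) == 0 or len(senders) == 0:
        return LRScore(ligand, receptor, sender_type, receiver_category, 0.0, 0, len(receivers))
    tree = cKDTree(receivers[["x_um", "y_um"]].to_numpy(dtype=float))
    d, _ = tree.query(senders[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
    in_range = senders.index[np.asarray(d) <= range_um]
    if len(in_range) == 0:
        return LRScore(ligand, receptor, sender_type, receiver_category, 0.0, 0, len(receivers))
    lig = trim_mean(expression.loc[in_range, ligand].to_numpy(), trim)
    rec = trim_mean(expression.loc[receivers.index, receptor].to_numpy(), trim)
    return LRScore(
        ligand,
        receptor,
        sender_type,
        receiver_category,
        float(max(lig, 0.0) * max(rec, 0.0)),
        int(len(in_range)),
        int(len(receivers)),
    )


def scale_incoming_signals(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each pathway (row) across receiver categories to [0, 1].

    Constant rows map to all zeros; idempotent on already-scaled rows with
    both 0 and 1 present.
    """
    mins = scores.min(axis=1)
    maxs = scores.max(axis=1)
    span = maxs - mins
    scaled = scores.sub(mins, axis=0).div(span.where(span > 0, 1.0), axis=0)
    scaled[span == 0] = 0.0
    return scaled
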
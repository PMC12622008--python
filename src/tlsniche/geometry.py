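"""TLS polygon construction, distance axes, and the per-TLS radial partition.

TLS instances are delimited by density-based spatial clustering of the
TLS-zone cells; each instance gets an alpha-shape-style concave hull with a
characteristic length scale (the convex hull in the infinite-length limit),
and hulls below a minimum area are discarded so that only mature TLS remain.
Distances are 2D Euclidean in μm.  A cell inside or on the boundary of a TLS
polygon has distance 0 to TLS; cells of the bronchi zone have distance 0 on
the bronchi axis, and all other cells get the mean distance to their 10
nearest bronchi-zone cells.  Each TLS is partitioned radially: inside cells
are split at the midpoint of the min-max-scaled centroid distance into core
and outer halves, and cells within 50 μm outside the polygon edge form the
surrounding ring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN


@dataclass
class TLSPolygon:
    """A mature TLS instance: simple polygon ring with area and centroid."""

    tls_id: int
    polygon: Polygon
    area: float
    centroid: tuple[float, float]

    @property
    def exterior_coords(self) -> list[tuple[float, float]]:
        return [(float(x), float(y)) for x, y in self.polygon.exterior.coords]


def _alpha_shape(points: np.ndarray, alpha: float) -> Polygon | None:
    """Alpha-shape concave hull: union of Delaunay triangles whose
    circumradius is at most ``alpha``.  Returns the largest polygon of the
    union, or None when no triangle qualifies."""
    if len(points) < 4:
        return None
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    pa = points[tri.simplices[:, 0]]
    pb = points[tri.simplices[:, 1]]
    pc = points[tri.simplices[:, 2]]
    a = np.linalg.norm(pb - pa, axis=1)
    b = np.linalg.norm(pc - pb, axis=1)
    c = np.linalg.norm(pa - pc, axis=1)
    s = (a + b + c) / 2.0
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
    keep = tri.simplices[circum_r <= alpha]
    if len(keep) == 0:
        return None
    triangles = [Polygon(points[simplex]) for simplex in keep]
    union = unary_union(triangles)
    if union.is_empty:
        return None
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    if union.geom_type != "Polygon" or union.area <= 0:
        return None
    # drop interior holes: a TLS is a filled structure
    return Polygon(union.exterior)


def build_tls_polygons(
    tls_cells: pd.DataFrame,
    group_eps: float = 50.0,
    concavity: float = 150.0,
    min_area: float = 5000.0,
) -> list[TLSPolygon]:
    """Group TLS-zone cells spatially and build a concave hull per group.

    Parameters
    ----------
    tls_cells
        Cell table subset containing only TLS-zone cells (columns ``x_um``,
        ``y_um``).
    group_eps
        DBSCAN radius (μm) delimiting separate TLS instances.
    concavity
        Characteristic length (μm) of the alpha shape; ``inf`` gives the
        convex hull.
    min_area
        Hulls with area strictly below this (μm²) are discarded, keeping
        only mature TLS.

    Returns polygons ordered by centroid (x, then y) with sequential ids.
    An input from which no hull survives yields an empty list with a
    warning, not an error.
    """
    if len(tls_cells) < 3:
        warnings.warn("fewer than 3 TLS-zone cells: no polygons built")
        return []
    xy = tls_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=group_eps, min_samples=3).fit_predict(xy)

    hulls: list[Polygon] = []
    for lab in sorted(set(labels) - {-1}):
        pts = xy[labels == lab]
        if len(pts) < 3:
            continue
        hull: Polygon | None = None
        if math.isfinite(concavity):
            hull = _alpha_shape(pts, concavity)
        if hull is None:
            convex = MultiPoint(pts).convex_hull
            if convex.geom_type != "Polygon":
                continue  # collinear group: degenerate, no area
            hull = convex
        if hull.area >= min_area and hull.is_valid:
            hulls.append(hull)

    if not hulls:
        warnings.warn("no TLS polygon survived the minimum-area filter")
        return []
    hulls.sort(key=lambda h: (h.centroid.x, h.centroid.y))
    return [
        TLSPolygon(
            tls_id=i,
            polygon=h,
            area=float(h.area),
            centroid=(float(h.centroid.x), float(h.centroid.y)),
        )
        for i, h in enumerate(hulls)
    ]


def distance_to_tls(
    cells: pd.DataFrame, polygons: list[TLSPolygon]
) -> pd.DataFrame:
    """Distance from every cell to the closest TLS polygon.

    Cells inside or on the boundary of a polygon get distance 0 and that
    polygon's id; other cells get the minimum Euclidean distance to any
    polygon boundary and the id of the nearest polygon.  With no polygons
    the axis is undefined: distances are NaN and ids -1.
    """
    n = len(cells)
    if not polygons:
        return pd.DataFrame(
            {"d_tls": np.full(n, np.nan), "tls_id": np.full(n, -1)},
            index=cells.index,
        )
    pts = shapely.points(cells[["x_um", "y_um"]].to_numpy(dtype=float))
    dmat = np.column_stack(
        [shapely.distance(pts, p.polygon) for p in polygons]
    )  # 0 inside or on boundary
    nearest = dmat.argmin(axis=1)
    d = dmat[np.arange(n), nearest]
    ids = np.array([polygons[j].tls_id for j in nearest])
    return pd.DataFrame({"d_tls": d, "tls_id": ids}, index=cells.index)


def distance_to_zone_cells(
    cells: pd.DataFrame,
    zones: pd.Series,
    zone: str = "bronchi",
    k: int = 10,
) -> pd.Series:
    """Mean distance to the ``k`` nearest cells of a zone (0 for members).

    ``zones`` is a per-cell zone label aligned to ``cells``.  Raises if the
    target zone holds fewer than ``k`` cells, since the k-nearest mean would
    be undefined as specified.
    """
    zones = zones.reindex(cells.index)
    member = (zones == zone).to_numpy()
    n_zone = int(member.sum())
    if n_zone < k:
        raise ValueError(
            f"zone {zone!r} has {n_zone} cells but k = {k} are required"
        )
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy[member])
    d = np.zeros(len(cells))
    if (~member).any():
        dists, _ = tree.query(xy[~member], k=k)
        d[~member] = np.atleast_2d(dists).mean(axis=1) if k > 1 else np.asarray(dists)
    return pd.Series(d, index=cells.index, name=f"d_{zone}")


def radial_partition(
    cells: pd.DataFrame,
    polygons: list[TLSPolygon],
    ring_width: float = 50.0,
    split: float = 0.5,
    split_mode: str = "value",
) -> pd.DataFrame:
    """Partition cells into TLS core / outer / surrounding-ring categories.

    For each TLS, cells inside (boundary inclusive) get the radial distance
    ``r`` to the polygon centroid, min-max scaled within that TLS to
    ``r_scaled`` in [0, 1] (0 when all inside cells are equidistant, e.g. a
    single cell).  With ``split_mode='value'`` (default) a cell is ``core``
    iff ``r_scaled <= split`` and ``outer`` otherwise; ``'count'`` splits at
    the per-TLS ``split`` quantile of ``r_scaled`` instead.  Cells outside
    every polygon whose distance to the nearest polygon edge lies in
    ``(0, ring_width]`` are ``surrounding``; all remaining cells are
    ``none``.

    Returns a frame with columns ``tls_id``, ``r_scaled``, ``ring_dist``
    and ``category`` indexed like ``cells``.
    """
    n = len(cells)
    out = pd.DataFrame(
        {
            "tls_id": np.full(n, -1),
            "r_scaled": np.full(n, np.nan),
            "ring_dist": np.full(n, np.nan),
            "category": np.full(n, "none", dtype=object),
        },
        index=cells.index,
    )
    if not polygons:
        return out

    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    pts = shapely.points(xy)
    inside_any = np.zeros(n, dtype=bool)
    for p in polygons:
        inside = shapely.covers(p.polygon, pts) & ~inside_any  # first id wins
        if not inside.any():
            continue
        inside_any |= inside
        cx, cy = p.centroid
        r = np.hypot(xy[inside, 0] - cx, xy[inside, 1] - cy)
        r_min, r_max = r.min(), r.max()
        r_scaled = np.zeros_like(r) if r_max == r_min else (r - r_min) / (r_max - r_min)
        if split_mode == "count":
            threshold = np.quantile(r_scaled, split)
        else:
            threshold = split
        cat = np.where(r_scaled <= threshold, "core", "outer")
        out.loc[cells.index[inside], "tls_id"] = p.tls_id
        out.loc[cells.index[inside], "r_scaled"] = r_scaled
        out.loc[cells.index[inside], "category"] = cat

    outside = ~inside_any
    if outside.any():
        dmat = np.column_stack(
            [shapely.distance(pts[outside], p.polygon) for p in polygons]
        )
        nearest = dmat.argmin(axis=1)
        edge_d = dmat[np.arange(int(outside.sum())), nearest]
        ring = (edge_d > 0) & (edge_d <= ring_width)
        idx = cells.index[outside]
        out.loc[idx[ring], "ring_dist"] = edge_d[ring]
        out.loc[idx[ring], "tls_id"] = np.array(
            [polygons[j].tls_id for j in nearest[ring]]
        )
        out.loc[idx[ring], "category"] = "surrounding"
    return out
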
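"""Independent brute-force reference implementations.

Every function here is a deliberately naive O(n²) (or worse) computation
used only to check the package's vectorized / tree-based code paths.  None
of them import from the modules they verify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def point_segment_distance(px, py, ax, ay, bx, by) -> float:
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    seg_len2 = vx * vx + vy * vy
    t = 0.0 if seg_len2 == 0 else max(0.0, min(1.0, (wx * vx + wy * vy) / seg_len2))
    cx, cy = ax + t * vx, ay + t * vy
    return float(np.hypot(px - cx, py - cy))


def point_in_ring(px, py, ring) -> bool:
    """Even-odd rule point-in-polygon with boundary counted as inside."""
    n = len(ring)
    inside = False
    for i in range(n - 1):
        ax, ay = ring[i]
        bx, by = ring[i + 1]
        if point_segment_distance(px, py, ax, ay, bx, by) < 1e-9:
            return True
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def distance_to_polygons(px, py, rings) -> float:
    """Min distance to any polygon; 0 if inside or on a boundary."""
    best = np.inf
    for ring in rings:
        if point_in_ring(px, py, ring):
            return 0.0
        for i in range(len(ring) - 1):
            ax, ay = ring[i]
            bx, by = ring[i + 1]
            best = min(best, point_segment_distance(px, py, ax, ay, bx, by))
    return best


def mean_knn_distance(px, py, zone_xy, k) -> float:
    d = np.sort(np.hypot(zone_xy[:, 0] - px, zone_xy[:, 1] - py))
    return float(d[:k].mean())


def capsule_relabel(cells: pd.DataFrame, k_meso: int, max_avg: float) -> pd.Series:
    """All-pairs capsule rule: True where the cell becomes capsule."""
    meso = cells[cells["cell_type"] == "mesothelial"][["x_um", "y_um"]].to_numpy()
    flags = []
    for _, row in cells.iterrows():
        d = np.sort(np.hypot(meso[:, 0] - row["x_um"], meso[:, 1] - row["y_um"]))
        flags.append(d[:k_meso].mean() <= max_avg)
    return pd.Series(flags, index=cells.index)


def radius_edges(cells: pd.DataFrame, radius: float) -> set:
    xy = cells[["x_um", "y_um"]].to_numpy()
    ids = cells.index.to_list()
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


def edge_type_tally(edges, types: pd.Series, zone_members: set, all_types) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=list(all_types), columns=list(all_types))
    for e in edges:
        u, v = tuple(e)
        if u in zone_members and v in zone_members:
            mat.loc[types[u], types[v]] += 1
            mat.loc[types[v], types[u]] += 1
    return mat


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    cut = int(len(v) * trim)
    v = v[cut: len(v) - cut] if cut else v
    return float(v.mean())


def lr_score_bruteforce(
    expression: pd.DataFrame,
    cells: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender_type: str,
    receiver_ids,
    range_um: float,
    trim: float,
) -> float:
    receivers = cells.loc[list(receiver_ids)]
    senders = cells[cells["cell_type"] == sender_type]
    in_range = []
    for sid, srow in senders.iterrows():
        for _, rrow in receivers.iterrows():
            if np.hypot(srow["x_um"] - rrow["x_um"], srow["y_um"] - rrow["y_um"]) <= range_um:
                in_range.append(sid)
                break
    if not in_range:
        return 0.0
    lig = trimmed_mean(expression.loc[in_range, ligand].to_numpy(), trim)
    rec = trimmed_mean(expression.loc[receivers.index, receptor].to_numpy(), trim)
    return max(lig, 0.0) * max(rec, 0.0)
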
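"""Tissue-zone assignment.

Zones (TLS, bronchi, vessel, adventitia, parenchyma, capsule, ...) are
contiguous regions of shared local cell composition.  External zone labels
are accepted as-is.  As a transparent stand-in for full neighborhood-model
clustering, this module offers k-nearest-neighbor cell-type composition
features followed by Gaussian-mixture clustering, with clusters renamed by
majority ground-truth zone when truth is available.  The capsule is then
separated by the distance-to-mesothelium rule: every cell within an average
of 100 μm of its 5 nearest mesothelial cells is assigned to the capsule
zone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

EXTERNAL = "external"
STANDIN = "standin_cluster"
RULE = "rule"


def zones_from_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Wrap externally supplied zone labels (a ``zone`` column) as assignments."""
    if "zone" not in cells.columns:
        raise ValueError("cell table has no 'zone' column to use as external zones")
    return pd.DataFrame(
        {"zone": cells["zone"].astype(str), "source": EXTERNAL}, index=cells.index
    )


def neighbor_composition_features(
    cells: pd.DataFrame, k_neighbors: int = 10
) -> pd.DataFrame:
    """Per-cell local cell-type composition.

    Each cell's feature vector is the fraction of each cell type among the
    cell itself and its ``k_neighbors`` nearest neighbors (k+1 cells total),
    so rows sum to 1.  Columns are the sorted unique cell types.
    """
    n = len(cells)
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {k_neighbors + 1} cells, got {n}"
        )
    xy = cells[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k_neighbors + 1)
    types = pd.Categorical(cells["cell_type"])
    codes = types.codes[idx]  # (n, k+1)
    n_types = len(types.categories)
    comp = np.zeros((n, n_types))
    for t in range(n_types):
        comp[:, t] = (codes == t).sum(axis=1)
    comp /= k_neighbors + 1
    order = np.argsort(types.categories)
    return pd.DataFrame(
        comp[:, order], index=cells.index, columns=types.categories[order]
    )


def cluster_zones(
    features: pd.DataFrame,
    n_zones: int,
    seed: int,
    true_zones: pd.Series | None = None,
) -> pd.DataFrame:
    """Partition cells into ``n_zones`` composition clusters.

    A Gaussian mixture on the composition features; deterministic for a
    given seed.  When ``true_zones`` is provided each cluster is renamed to
    the majority true zone of its members (several clusters may map to the
    same zone name); otherwise zones are named ``zone_0`` .. ``zone_{n-1}``.
    """
    n = len(features)
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if n_zones > n:
        raise ValueError(f"n_zones = {n_zones} exceeds the number of cells ({n})")
    if n_zones == 1:
        labels = np.zeros(n, dtype=int)
    else:
        gm = GaussianMixture(
            n_components=n_zones,
            covariance_type="diag",
            random_state=seed,
            n_init=1,
            reg_covar=1e-6,
        )
        labels = gm.fit_predict(features.to_numpy())
    if true_zones is not None:
        truth = true_zones.reindex(features.index)
        mapping = {}
        for lab in np.unique(labels):
            members = truth[labels == lab]
            # majority vote; deterministic alphabetic tie-break
            mapping[lab] = members.value_counts().sort_index().idxmax()
        names = np.array([mapping[lab] for lab in labels], dtype=object)
    else:
        names = np.array([f"zone_{lab}" for lab in labels], dtype=object)
    return pd.DataFrame({"zone": names, "source": STANDIN}, index=features.index)


def split_capsule(
    cells: pd.DataFrame,
    zones: pd.DataFrame,
    k_meso: int = 5,
    max_avg_dist: float = 100.0,
) -> pd.DataFrame:
    """Relabel to ``capsule`` every cell near the mesothelial lining.

    A cell whose mean Euclidean distance to its ``k_meso`` nearest
    mesothelial cells is at most ``max_avg_dist`` μm (inclusive — "within")
    becomes capsule; all other assignments are unchanged.  Idempotent.
    """
    meso = cells[cells["cell_type"] == "mesothelial"]
    if len(meso) < k_meso:
        raise ValueError(
            f"capsule rule needs at least {k_meso} mesothelial cells; "
            f"found {len(meso)} (short by {k_meso - len(meso)})"
        )
    tree = cKDTree(meso[["x_um", "y_um"]].to_numpy())
    dists, _ = tree.query(cells[["x_um", "y_um"]].to_numpy(), k=k_meso)
    mean_d = np.atleast_2d(dists).mean(axis=1) if k_meso > 1 else np.asarray(dists)
    out = zones.copy()
    near = mean_d <= max_avg_dist
    out.loc[cells.index[near], "zone"] = "capsule"
    out.loc[cells.index[near], "source"] = RULE
    return out
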
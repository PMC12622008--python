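"""Synthetic structured lung-like tissue with known ground truth.

The generator lays out a rectangular tissue field containing tertiary
lymphoid structures (TLS, modeled as dense discs of B cells and progenitor
CD4 T cells), bronchi (epithelial annuli around an empty lumen), blood
vessels (endothelial discs), a mesothelium-lined capsule strip along the
bottom field edge, and parenchyma everywhere else.  Cell placement is a
Poisson point process per structure at configurable density; cell types are
drawn from per-structure mixtures.

Expression follows a distance-decay model for CD4 T cells: a gene of class
``progenitor`` has expected count ``a * exp(-d_tls / lam) + b`` where
``d_tls`` is the true distance to the nearest TLS disc, and a gene of class
``effector`` decays the same way with the distance to the nearest bronchus
annulus.  Ligand-class genes are expressed by antigen-presenting cells
(macrophages, cDC2) and decay with distance to the nearest TLS *center*, so
ligand availability peaks in the TLS core.  Counts are drawn
negative-binomially with configurable dispersion (infinite dispersion gives
the Poisson limit).  Every quantity needed to verify downstream geometry —
structure centers and radii, true per-cell distances, true gradient
parameters — is recorded in a :class:`SyntheticTruth`.

A separate generator produces droplet hashtag-count matrices with known
singlet / doublet / empty composition for testing demultiplexing rules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import APC_TYPES, CD4_TYPES, STRUCTURAL_MARKER_TYPES, SimConfig

_MAX_PLACEMENT_ATTEMPTS = 2000


class PlacementError(RuntimeError):
    """Raised when a structure cannot be placed without overlap."""


@dataclass
class Structure:
    kind: str  # "tls" | "bronchus" | "vessel"
    index: int
    cx: float
    cy: float
    radius: float  # disc radius; for bronchi, the lumen radius
    wall: float = 0.0  # annulus width (bronchi only)

    @property
    def outer_radius(self) -> float:
        return self.radius + self.wall


@dataclass
class SyntheticTruth:
    """Ground truth for a generated tissue or hashtag experiment."""

    structures: list[Structure] = field(default_factory=list)
    capsule_depth: float = 0.0
    field_width: float = 0.0
    field_height: float = 0.0
    d_tls_true: pd.Series | None = None  # μm, indexed by cell_id
    d_bronchi_true: pd.Series | None = None
    gradient_params: dict[str, dict[str, float]] = field(default_factory=dict)
    hashtag_labels: pd.DataFrame | None = None  # droplet truth

    def to_json(self, path: str | Path) -> None:
        payload: dict[str, Any] = {
            "field_width": self.field_width,
            "field_height": self.field_height,
            "capsule_depth": self.capsule_depth,
            "structures": [
                {
                    "kind": s.kind,
                    "index": s.index,
                    "cx": s.cx,
                    "cy": s.cy,
                    "radius": s.radius,
                    "wall": s.wall,
                }
                for s in self.structures
            ],
            "gradient_params": self.gradient_params,
        }
        if self.d_tls_true is not None:
            payload["d_tls_true"] = self.d_tls_true.round(6).to_dict()
        if self.d_bronchi_true is not None:
            payload["d_bronchi_true"] = self.d_bronchi_true.round(6).to_dict()
        if self.hashtag_labels is not None:
            payload["hashtag_labels"] = self.hashtag_labels.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _place_structures(config: SimConfig, rng: np.random.Generator) -> list[Structure]:
    """Rejection-sample non-overlapping structure centers inside the field.

    Structures keep a small margin from each other, from the field edges and
    from the capsule strip so that analytic truth distances stay simple.
    """
    margin = 20.0
    placed: list[Structure] = []
    plan: list[tuple[str, int, float, float]] = []
    for i in range(config.n_tls):
        r = max(10.0, rng.normal(config.tls_radius_mean, config.tls_radius_sd))
        plan.append(("tls", i, r, 0.0))
    for i in range(config.n_bronchi):
        plan.append(("bronchus", i, config.bronchus_radius, config.bronchus_wall))
    for i in range(config.n_vessels):
        plan.append(("vessel", i, config.vessel_radius, 0.0))

    y_max_allowed = config.field_height - config.capsule_depth
    for kind, index, radius, wall in plan:
        outer = radius + wall
        if (
            config.field_width < 2 * (outer + margin)
            or y_max_allowed < 2 * (outer + margin)
        ):
            raise PlacementError(
                f"could not place {kind} #{index}: structure of radius "
                f"{outer:.0f} μm does not fit in the field"
            )
        ok = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cx = rng.uniform(outer + margin, config.field_width - outer - margin)
            cy = rng.uniform(outer + margin, y_max_allowed - outer - margin)
            if any(
                math.hypot(cx - s.cx, cy - s.cy) < outer + s.outer_radius + margin
                for s in placed
            ):
                continue
            placed.append(Structure(kind, index, cx, cy, radius, wall))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place {kind} #{index} (radius {outer:.0f} μm) "
                f"without overlap after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return placed


def _sample_in_disc(
    rng: np.random.Generator, n: int, cx: float, cy: float, r: float
) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = r * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])


def _sample_in_annulus(
    rng: np.random.Generator, n: int, cx: float, cy: float, r0: float, r1: float
) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = np.sqrt(rng.uniform(r0**2, r1**2, n))
    return np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])


def _true_distances(
    xy: np.ndarray, structures: list[Structure]
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic distance to the nearest TLS disc and bronchus annulus."""
    n = len(xy)
    d_tls = np.full(n, np.inf)
    d_bronchi = np.full(n, np.inf)
    for s in structures:
        rho = np.hypot(xy[:, 0] - s.cx, xy[:, 1] - s.cy)
        if s.kind == "tls":
            d_tls = np.minimum(d_tls, np.maximum(0.0, rho - s.radius))
        elif s.kind == "bronchus":
            inside_lumen = np.maximum(0.0, s.radius - rho)
            outside = np.maximum(0.0, rho - s.outer_radius)
            d_bronchi = np.minimum(d_bronchi, inside_lumen + outside)
    return d_tls, d_bronchi


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with mean mu and NB size ``dispersion``.

    variance = mu + mu^2 / dispersion; dispersion = inf gives Poisson.
    """
    mu = np.maximum(mu, 0.0)
    if math.isinf(dispersion):
        return rng.poisson(mu)
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def generate_tissue(
    config: SimConfig,
) -> tuple[pd.DataFrame, ad.AnnData, SyntheticTruth]:
    """Generate a synthetic tissue: cell table, counts, and ground truth.

    Returns
    -------
    cells : DataFrame with columns cell_id, x_um, y_um, cell_type,
        true_zone, sample (index = cell_id).
    expression : AnnData of shape (n_cells, n_genes) with integer counts in
        ``X`` (CSR) and ``var['gene_class']``.
    truth : SyntheticTruth with structure geometry, analytic per-cell
        distances and the gradient parameters used.
    """
    rng = np.random.default_rng(config.seed)
    structures = _place_structures(config, rng)
    density = config.cell_density_per_structure
    mixtures = config.celltype_mixture_per_structure

    frames: list[pd.DataFrame] = []

    def _cells_for(kind: str, xy: np.ndarray, zone: str) -> None:
        if len(xy) == 0:
            return
        mix = mixtures[kind]
        types = rng.choice(
            list(mix.keys()), size=len(xy), p=np.asarray(list(mix.values()))
        )
        frames.append(
            pd.DataFrame(
                {
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                    "cell_type": types,
                    "true_zone": zone,
                }
            )
        )

    for s in structures:
        if s.kind == "tls":
            area = math.pi * s.radius**2
            n = rng.poisson(density["tls"] * area / 1e4)
            _cells_for("tls", _sample_in_disc(rng, n, s.cx, s.cy, s.radius), "TLS")
        elif s.kind == "bronchus":
            area = math.pi * (s.outer_radius**2 - s.radius**2)
            n = rng.poisson(density["bronchus"] * area / 1e4)
            xy = _sample_in_annulus(rng, n, s.cx, s.cy, s.radius, s.outer_radius)
            _cells_for("bronchus", xy, "bronchi")
        else:
            area = math.pi * s.radius**2
            n = rng.poisson(density["vessel"] * area / 1e4)
            _cells_for("vessel", _sample_in_disc(rng, n, s.cx, s.cy, s.radius), "vessel")

    # capsule strip along the bottom edge
    cap_area = config.field_width * config.capsule_depth
    n_cap = rng.poisson(density["capsule"] * cap_area / 1e4)
    cap_xy = np.column_stack(
        [
            rng.uniform(0, config.field_width, n_cap),
            rng.uniform(
                config.field_height - config.capsule_depth, config.field_height, n_cap
            ),
        ]
    )
    _cells_for("capsule", cap_xy, "capsule")

    # parenchyma: uniform over the field minus structures and capsule
    par_area = config.field_width * (config.field_height - config.capsule_depth)
    n_par = rng.poisson(density["parenchyma"] * par_area / 1e4)
    par_pts: list[np.ndarray] = []
    need = n_par
    while need > 0:
        cand = np.column_stack(
            [
                rng.uniform(0, config.field_width, need * 2 + 8),
                rng.uniform(0, config.field_height - config.capsule_depth, need * 2 + 8),
            ]
        )
        keep = np.ones(len(cand), dtype=bool)
        for s in structures:
            rho = np.hypot(cand[:, 0] - s.cx, cand[:, 1] - s.cy)
            keep &= rho > s.outer_radius
        cand = cand[keep][:need]
        if len(cand):
            par_pts.append(cand)
            need -= len(cand)
    if par_pts:
        _cells_for("parenchyma", np.concatenate(par_pts), "parenchyma")

    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["x_um", "y_um", "cell_type", "true_zone"]
    )
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(cells))])
    cells["sample"] = "sim"
    cells = cells.set_index("cell_id", drop=False)

    xy = cells[["x_um", "y_um"]].to_numpy()
    d_tls, d_bronchi = _true_distances(xy, structures)
    # no TLS / no bronchi in the field: the axis is undefined, not infinite
    d_tls = np.where(np.isinf(d_tls), np.nan, d_tls)
    d_bronchi = np.where(np.isinf(d_bronchi), np.nan, d_bronchi)

    counts = _simulate_expression(config, cells, d_tls, d_bronchi, structures, rng)

    genes = [g for g, _ in config.gene_panel]
    classes = [c for _, c in config.gene_panel]
    expression = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(index=cells.index.copy()),
        var=pd.DataFrame({"gene_class": classes}, index=pd.Index(genes, name="gene")),
    )

    truth = SyntheticTruth(
        structures=structures,
        capsule_depth=config.capsule_depth,
        field_width=config.field_width,
        field_height=config.field_height,
        d_tls_true=pd.Series(d_tls, index=cells.index, name="d_tls_true"),
        d_bronchi_true=pd.Series(d_bronchi, index=cells.index, name="d_bronchi_true"),
        gradient_params={
            "progenitor": {
                "a": config.gradient_amplitude,
                "lam": config.gradient_scale,
                "b": config.baseline,
                "axis": 0,  # 0 = d_tls
            },
            "effector": {
                "a": config.gradient_amplitude,
                "lam": config.gradient_scale,
                "b": config.baseline,
                "axis": 1,  # 1 = d_bronchi
            },
        },
    )
    return cells, expression, truth


def _simulate_expression(
    config: SimConfig,
    cells: pd.DataFrame,
    d_tls: np.ndarray,
    d_bronchi: np.ndarray,
    structures: list[Structure],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(cells)
    a, lam, b = config.gradient_amplitude, config.gradient_scale, config.baseline
    is_cd4 = cells["cell_type"].isin(CD4_TYPES).to_numpy()
    is_apc = cells["cell_type"].isin(APC_TYPES).to_numpy()

    # distance from each cell to the nearest TLS *center* (ligand axis)
    tls_centers = [(s.cx, s.cy) for s in structures if s.kind == "tls"]
    if tls_centers:
        xy = cells[["x_um", "y_um"]].to_numpy()
        d_center = np.min(
            [np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) for cx, cy in tls_centers], axis=0
        )
    else:
        d_center = np.full(n, np.nan)

    counts = np.zeros((n, len(config.gene_panel)), dtype=np.int64)
    structural_cycle = 0
    for j, (_, cls) in enumerate(config.gene_panel):
        mu = np.full(n, b)
        if cls == "progenitor":
            grad = a * np.exp(-np.nan_to_num(d_tls, nan=np.inf) / lam) + b
            mu = np.where(is_cd4, grad, b)
        elif cls == "effector":
            grad = a * np.exp(-np.nan_to_num(d_bronchi, nan=np.inf) / lam) + b
            mu = np.where(is_cd4, grad, b)
        elif cls == "structural":
            marker_type = STRUCTURAL_MARKER_TYPES[
                structural_cycle % len(STRUCTURAL_MARKER_TYPES)
            ]
            structural_cycle += 1
            mu = np.where(
                cells["cell_type"].to_numpy() == marker_type,
                config.structural_marker_mean,
                b,
            )
        elif cls == "housekeeping":
            mu = np.full(n, config.housekeeping_mean)
        elif cls == "ligand":
            grad = a * np.exp(-np.nan_to_num(d_center, nan=np.inf) / lam)
            mu = np.where(is_apc, grad, 0.0)
        elif cls == "receptor":
            mu = np.where(is_cd4, config.receptor_mean, 0.0)
        counts[:, j] = _draw_counts(rng, mu, config.dispersion)
    return counts


def gradient_recovery_config(
    seed: int = 1,
    gradient_amplitude: float = 20.0,
    gradient_scale: float = 100.0,
    baseline: float = 1.0,
    dispersion: float = math.inf,
) -> SimConfig:
    """A compact, CD4-rich tissue for gradient-recovery studies.

    A 2 × 2 mm field at elevated parenchymal density and CD4 fraction so
    that roughly five thousand CD4 T cells populate the distance axes; the
    exponential-gradient parameters default to a = 20 counts, lam = 100 μm,
    b = 1 count with Poisson noise.
    """
    mixtures = {
        "tls": {
            "B": 0.45,
            "CD4_Th0": 0.40,
            "CD4_other": 0.05,
            "macrophage": 0.05,
            "cDC2": 0.05,
        },
        "bronchus": {"epithelial_bronchus": 0.85, "CD4_Th2": 0.15},
        "vessel": {"endothelial": 0.90, "other": 0.10},
        "capsule": {"mesothelial": 0.80, "other": 0.20},
        "parenchyma": {
            "CD4_Th2": 0.28,
            "CD4_other": 0.17,
            "B": 0.05,
            "macrophage": 0.12,
            "cDC2": 0.05,
            "endothelial": 0.08,
            "other": 0.25,
        },
    }
    density = {
        "tls": 60.0,
        "bronchus": 40.0,
        "vessel": 25.0,
        "capsule": 25.0,
        "parenchyma": 25.0,
    }
    return SimConfig(
        field_width=2000.0,
        field_height=2000.0,
        cell_density_per_structure=density,
        celltype_mixture_per_structure=mixtures,
        gradient_amplitude=gradient_amplitude,
        gradient_scale=gradient_scale,
        baseline=baseline,
        dispersion=dispersion,
        seed=seed,
    )


def generate_hashtag_counts(
    n_singlets: int,
    n_doublets: int,
    n_empty: int,
    signal_mean: float,
    background_mean: float,
    seed: int,
    n_hashtags: int = 10,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a droplet × hashtag count matrix with known composition.

    ``n_singlets`` droplets are generated *per hashtag*: each has counts
    Poisson(signal_mean) for its own hashtag and Poisson(background_mean) for
    all others.  Doublet droplets carry two high hashtags; empty droplets
    only background.  Returns the count matrix (droplets × hashtags) and a
    :class:`SyntheticTruth` whose ``hashtag_labels`` frame records the true
    label of every droplet (``singlet`` with its hashtag, ``doublet`` with
    both, or ``empty``).
    """
    if n_hashtags < 1:
        raise ValueError("at least one hashtag is required")
    if signal_mean <= 0 or background_mean < 0:
        raise ValueError("signal_mean must be > 0 and background_mean >= 0")
    if signal_mean <= background_mean:
        raise ValueError("signal_mean must exceed background_mean")
    if n_singlets < 0 or n_doublets < 0 or n_empty < 0:
        raise ValueError("droplet counts must be >= 0")
    if n_doublets > 0 and n_hashtags < 2:
        raise ValueError("doublets require at least two hashtags")

    rng = np.random.default_rng(seed)
    hashtags = [f"HTO{h + 1}" for h in range(n_hashtags)]
    rows: list[np.ndarray] = []
    labels: list[str] = []
    members: list[str] = []

    for h in range(n_hashtags):
        block = rng.poisson(background_mean, size=(n_singlets, n_hashtags)).astype(
            np.int64
        )
        block[:, h] = rng.poisson(signal_mean, size=n_singlets)
        rows.append(block)
        labels.extend(["singlet"] * n_singlets)
        members.extend([hashtags[h]] * n_singlets)

    for _ in range(n_doublets):
        h1, h2 = rng.choice(n_hashtags, size=2, replace=False)
        row = rng.poisson(background_mean, size=n_hashtags).astype(np.int64)
        row[h1] = rng.poisson(signal_mean)
        row[h2] = rng.poisson(signal_mean)
        rows.append(row[None, :])
        labels.append("doublet")
        members.append(f"{hashtags[h1]}+{hashtags[h2]}")

    if n_empty:
        rows.append(rng.poisson(background_mean, size=(n_empty, n_hashtags)).astype(np.int64))
        labels.extend(["empty"] * n_empty)
        members.extend([""] * n_empty)

    matrix = np.concatenate(rows, axis=0) if rows else np.zeros((0, n_hashtags), int)
    index = pd.Index([f"d{i:06d}" for i in range(len(matrix))], name="cell_id")
    counts = pd.DataFrame(matrix, index=index, columns=hashtags)
    truth = SyntheticTruth(
        hashtag_labels=pd.DataFrame(
            {"label": labels, "hashtag": members}, index=index
        )
    )
    return counts, truth
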
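"""Readers and writers for the pipeline's standard formats.

Cell tables are CSV/TSV/Parquet with required columns ``cell_id``,
``x_um``, ``y_um``, ``cell_type`` and optional ``zone`` / ``sample``;
coordinates are continuous μm with y increasing downward (image
convention).  Counts are MatrixMarket MTX (genes × cells, with
``genes.tsv`` and ``barcodes.tsv``) or a dense cells × genes CSV.  Derived
results are written as CSVs, TLS polygons as GeoJSON in μm coordinates,
and a JSON run log carrying the resolved configuration and its hash.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .geometry import TLSPolygon

REQUIRED_CELL_COLUMNS = ("cell_id", "x_um", "y_um", "cell_type")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell table (CSV, TSV, or Parquet)."""
    path = Path(path)
    if path.suffix == ".parquet":
        cells = pd.read_parquet(path)
    elif path.suffix in (".tsv", ".txt"):
        cells = pd.read_csv(path, sep="\t")
    else:
        cells = pd.read_csv(path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required columns: {missing}")
    cells["cell_id"] = cells["cell_id"].astype(str)
    if cells["cell_id"].duplicated().any():
        raise ValueError(f"cell table {path} has duplicate cell_id values")
    return cells.set_index("cell_id", drop=False)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        cells.to_parquet(path, index=False)
    else:
        cells.to_csv(path, index=False)


def read_counts(
    path: str | Path, cell_table: pd.DataFrame | None = None
) -> ad.AnnData:
    """Read a counts matrix as AnnData (cells × genes).

    ``path`` is either a directory holding ``matrix.mtx`` (genes × cells),
    ``genes.tsv`` and ``barcodes.tsv``, or a dense CSV with cells as rows
    (first column = cell id) and genes as columns.  When ``cell_table`` is
    given, the cells are aligned to its order; any mismatch between
    barcodes and table cell ids is an error.
    """
    path = Path(path)
    if path.is_dir():
        mat = scipy_io.mmread(path / "matrix.mtx").tocsr()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
        var = pd.DataFrame(index=pd.Index(genes[0].astype(str), name="gene"))
        if genes.shape[1] > 1:
            var["gene_class"] = genes[1].astype(str).to_numpy()
        adata = ad.AnnData(
            X=mat.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="cell_id")),
            var=var,
        )
    else:
        df = pd.read_csv(path, index_col=0)
        adata = ad.AnnData(
            X=sparse.csr_matrix(df.to_numpy()),
            obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="cell_id")),
            var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene")),
        )
    if cell_table is not None:
        table_ids = pd.Index(cell_table["cell_id"].astype(str))
        if set(adata.obs_names) != set(table_ids):
            extra = sorted(set(adata.obs_names) - set(table_ids))[:3]
            absent = sorted(set(table_ids) - set(adata.obs_names))[:3]
            raise ValueError(
                "barcodes do not match the cell table "
                f"(e.g. extra {extra}, missing {absent})"
            )
        adata = adata[table_ids.to_list()].copy()
    return adata


def write_counts(expression: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as MatrixMarket (genes × cells) plus gene/barcode TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = expression.X
    mat = X.T if sparse.issparse(X) else sparse.csr_matrix(np.asarray(X)).T
    scipy_io.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(mat))
    genes = pd.DataFrame({"gene": expression.var_names})
    if "gene_class" in expression.var.columns:
        genes["gene_class"] = expression.var["gene_class"].to_numpy()
    genes.to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(expression.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def polygons_to_geojson(polygons: list[TLSPolygon]) -> dict[str, Any]:
    return {
        "type": "FeatureCollection",
        "crs_note": "coordinates in μm, y increases downward",
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "tls_id": p.tls_id,
                    "area_um2": p.area,
                    "centroid": [p.centroid[0], p.centroid[1]],
                },
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in p.exterior_coords]],
                },
            }
            for p in polygons
        ],
    }


def write_polygons(polygons: list[TLSPolygon], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(polygons_to_geojson(polygons), fh, indent=1)


def read_polygons(path: str | Path) -> list[TLSPolygon]:
    from shapely.geometry import Polygon

    with open(path) as fh:
        gj = json.load(fh)
    polygons = []
    for feat in gj["features"]:
        ring = feat["geometry"]["coordinates"][0]
        poly = Polygon(ring)
        polygons.append(
            TLSPolygon(
                tls_id=int(feat["properties"]["tls_id"]),
                polygon=poly,
                area=float(feat["properties"]["area_um2"]),
                centroid=tuple(feat["properties"]["centroid"]),
            )
        )
    return polygons


def write_run_log(
    outdir: str | Path, config_dict: dict[str, Any], config_hash: str, seed: int
) -> None:
    payload = {"config": config_dict, "config_hash": config_hash, "seed": seed}
    with open(Path(outdir) / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
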
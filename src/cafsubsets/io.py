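"""Readers and writers for the pipeline's interchange formats.

* Event / cell / survival tables: CSV, UTF-8, header row, '.' decimal.
* Tumour-region geometry: GeoJSON (RFC 7946) with coordinates in um in
  a per-core local frame (origin at the core bounding-box corner);
  polygon rings must be closed and simple.
* Expression matrices: MatrixMarket triplets (1-based indices) with
  genes.tsv / cells.tsv sidecars, or dense CSV.

All writers are atomic (temp file + rename) and every artifact
round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon, mapping, shape

from .profiles import SchemaError

__all__ = [
    "write_table_csv",
    "read_table_csv",
    "write_regions_geojson",
    "read_regions_geojson",
    "write_expression_mtx",
    "read_expression_mtx",
    "atomic_write",
]


def atomic_write(path: str | Path, write_fn) -> Path:
    """Write a file atomically: temp file in the same directory + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # keep the real suffix so suffix-sensitive writers (mmwrite) behave
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.stem}.",
                               suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_table_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 CSV with a header row."""
    return atomic_write(path, lambda p: table.to_csv(p, index=False))


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_regions_geojson(regions: list[Polygon], path: str | Path,
                          core_id: str | None = None) -> Path:
    """Write tumour regions as a GeoJSON FeatureCollection (um coords)."""
    features = []
    for i, poly in enumerate(regions):
        props = {"region_index": i}
        if core_id is not None:
            props["core_id"] = core_id
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": mapping(poly),
        })
    doc = {"type": "FeatureCollection", "features": features}
    return atomic_write(
        path, lambda p: p.write_text(json.dumps(doc), encoding="utf-8"))


def read_regions_geojson(path: str | Path) -> list[Polygon]:
    """Read and validate tumour regions from GeoJSON.

    Every polygon ring must be explicitly closed (first == last
    coordinate) and the polygon simple; violations name the offending
    feature index.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("GeoJSON root must be a FeatureCollection")
    regions = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"feature {i}: geometry must be a Polygon")
        for ring in geom["coordinates"]:
            if len(ring) < 4 or ring[0] != ring[-1]:
                raise SchemaError(f"feature {i}: ring not closed")
        poly = shape(geom)
        if not poly.is_valid:
            raise SchemaError(f"feature {i}: polygon not simple/valid")
        regions.append(poly)
    return regions


def write_expression_mtx(adata: ad.AnnData, out_dir: str | Path) -> Path:
    """Write counts as MatrixMarket triplets with gene/cell sidecars.

    Produces ``matrix.mtx`` (genes x cells, 1-based coordinate format),
    ``genes.tsv`` and ``cells.tsv`` plus ``obs.csv`` with cell metadata.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    mat = X.T.tocoo()  # genes x cells
    atomic_write(out / "matrix.mtx",
                 lambda p: spio.mmwrite(str(p), mat, field="integer"))
    # mmwrite appends .mtx if missing; tmp names keep custom suffixes safe
    atomic_write(out / "genes.tsv", lambda p: p.write_text(
        "".join(f"{g}\n" for g in adata.var_names), encoding="utf-8"))
    atomic_write(out / "cells.tsv", lambda p: p.write_text(
        "".join(f"{c}\n" for c in adata.obs_names), encoding="utf-8"))
    if len(adata.obs.columns):
        atomic_write(out / "obs.csv",
                     lambda p: adata.obs.to_csv(p, index=True))
    return out


def read_expression_mtx(in_dir: str | Path) -> ad.AnnData:
    """Read an MTX triplet directory back into AnnData (cells x genes).

    Explicitly stored zero entries violate the sparse-triplet contract
    and are rejected.
    """
    in_dir = Path(in_dir)
    mat = spio.mmread(in_dir / "matrix.mtx")
    if sparse.issparse(mat) and np.any(mat.data == 0):
        raise SchemaError("matrix.mtx contains explicitly stored zero entries")
    genes = (in_dir / "genes.tsv").read_text(encoding="utf-8").split()
    cells = (in_dir / "cells.tsv").read_text(encoding="utf-8").split()
    X = sparse.csr_matrix(mat.T)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )
    obs_path = in_dir / "obs.csv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, index_col=0)
        adata.obs = obs.loc[adata.obs_names]
    return adata
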
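"""File formats: cell tables, spot matrices, zone maps, rasters.

Cell tables go to CSV or Parquet; spot matrices to MatrixMarket with
barcodes/features TSVs and a positions CSV (spot id, array row/col, physical
x/y in µm); zone maps to GeoJSON (µm coordinates, origin top-left, y
increasing downward); rasters to OME-TIFF with named channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse
from shapely.geometry import Polygon, mapping, shape

from .synth.raster import ColocRaster
from .synth.spots import SpotTable


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        cells.to_parquet(path, index=False)
    else:
        cells.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_spot_table(table: SpotTable, directory: str | Path) -> None:
    """MTX (genes x spots, integer) + barcodes.tsv + features.tsv + positions.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(table.counts, dtype=np.int64).T)
    scio.mmwrite(directory / "matrix.mtx", mat)
    pd.Series(table.spots["spot_id"]).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(table.genes).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False)
    cols = [c for c in ("spot_id", "row", "col", "x", "y", "sample", "zone",
                        "region") if c in table.spots.columns]
    table.spots[cols].to_csv(directory / "positions.csv", index=False)
    (directory / "lattice.txt").write_text(table.lattice + "\n")


def read_spot_table(directory: str | Path) -> SpotTable:
    directory = Path(directory)
    mat = scio.mmread(directory / "matrix.mtx").tocsr().T
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t",
                           header=None)[0].tolist()
    features = pd.read_csv(directory / "features.tsv", sep="\t",
                           header=None)[0].tolist()
    spots = pd.read_csv(directory / "positions.csv")
    if list(spots["spot_id"]) != barcodes:
        spots = spots.set_index("spot_id").loc[barcodes].reset_index()
    lattice_file = directory / "lattice.txt"
    lattice = lattice_file.read_text().strip() if lattice_file.exists() else "hex"
    return SpotTable(counts=np.asarray(mat.todense(), dtype=float),
                     genes=features, spots=spots, lattice=lattice)


def write_zone_map(zones: dict[str, Polygon], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"name": name},
         "geometry": mapping(poly)}
        for name, poly in zones.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection",
                   "coordinate_units": "micrometre",
                   "features": features}, fh)


def read_zone_map(path: str | Path) -> dict[str, Polygon]:
    with open(path) as fh:
        geo = json.load(fh)
    return {f["properties"]["name"]: shape(f["geometry"])
            for f in geo["features"]}


def write_raster(raster: ColocRaster, path: str | Path) -> None:
    import tifffile

    channels = list(raster.channels)
    stack = np.stack([raster.channels[c] for c in channels]).astype(np.float32)
    tifffile.imwrite(path, stack,
                     metadata={"axes": "CYX", "Channel": {"Name": channels},
                               "PhysicalSizeX": raster.um_per_px,
                               "PhysicalSizeY": raster.um_per_px})


def read_raster(path: str | Path,
                channel_names: list[str] | None = None) -> ColocRaster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        um = 1.0
        names = channel_names
        meta = tf.shaped_metadata or tf.imagej_metadata
        if isinstance(meta, (list, tuple)) and meta:
            meta = meta[0]
        if isinstance(meta, dict):
            um = float(meta.get("PhysicalSizeX", 1.0))
            if names is None:
                ch = meta.get("Channel", {})
                names = ch.get("Name") if isinstance(ch, dict) else None
    if stack.ndim == 2:
        stack = stack[None]
    if names is None:
        names = [f"ch{i}" for i in range(stack.shape[0])]
    return ColocRaster(channels={n: stack[i] for i, n in enumerate(names)},
                       um_per_px=um)
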
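"""Plain-text file I/O: ESRI ASCII grids for rasters, GeoJSON for vectors.

Rasters use the ASCII grid format (``.asc``) so outputs stay text and
round-trip exactly (values serialised with repr-level precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grids import GridMismatchError, GridSpec, RasterGrid

__all__ = ["write_raster", "read_raster", "write_geojson_lines", "read_geojson_lines"]

_NODATA = -9999.0


def write_raster(path, raster: RasterGrid) -> Path:
    """Write a raster as an ESRI ASCII grid (text)."""
    path = Path(path)
    spec = raster.spec
    vals = np.asarray(raster.values, dtype=float).copy()
    vals[~raster.valid_mask] = _NODATA
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x:.17g}\n"
        f"yllcorner {spec.origin_y - spec.height:.17g}\n"
        f"cellsize {spec.resolution:.17g}\n"
        f"NODATA_value {_NODATA:.17g}\n"
    )
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in vals)
    path.write_text(header + body + "\n")
    return path


def read_raster(path, expect_spec: GridSpec | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid; optionally validate against a session grid."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols",
        "nrows",
        "xllcorner",
        "yllcorner",
        "cellsize",
        "nodata_value",
    ):
        k, v = lines[i].split()
        header[k.lower()] = float(v)
        i += 1
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        resolution=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + int(header["nrows"]) * header["cellsize"],
    )
    if expect_spec is not None and spec != expect_spec:
        raise GridMismatchError(f"raster grid {spec} does not match session grid {expect_spec}")
    vals = np.array([[float(v) for v in line.split()] for line in lines[i:] if line.strip()])
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    return RasterGrid(spec, vals, name=Path(path).stem)


def write_geojson_lines(path, geometries, properties=None) -> Path:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    path = Path(path)
    feats = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties else {"id": i}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path


def read_geojson_lines(path) -> list:
    data = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in data["features"]]
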
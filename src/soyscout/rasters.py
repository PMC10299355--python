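"""Lightweight georeferenced raster and vector I/O.

Rasters are written as PNG with a JSON sidecar carrying the world metadata
(planar origin in meters, pixel size, y-axis orientation, and for float data
the linear value scaling used to pack it into 16-bit samples).  Block layouts
travel as GeoJSON polygons and grid counts as ``x,y,count`` CSV — the
exchange format shared by the variogram and SADIE stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape


@dataclass
class Raster:
    """In-memory raster: ``data[row, col]`` with y increasing with row."""

    data: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0

    @property
    def shape(self):
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of pixel centers, same shape as data."""
        h, w = self.data.shape[:2]
        xs = self.origin_x + (np.arange(w) + 0.5) * self.pixel_size
        ys = self.origin_y + (np.arange(h) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(path, raster: Raster) -> None:
    """Write a raster as PNG + sidecar.

    uint8 data (2D or HxWx3) is stored directly; bool as 0/255; float data is
    linearly packed into uint16 with the (vmin, vmax) recorded in the sidecar.
    """
    path = Path(path)
    data = raster.data
    meta = {
        "origin_x": raster.origin_x,
        "origin_y": raster.origin_y,
        "pixel_size": raster.pixel_size,
        "y_axis": "up",
        "dtype": str(data.dtype),
    }
    if data.dtype == np.uint8:
        img = data
    elif data.dtype == bool:
        img = (data.astype(np.uint8)) * 255
    elif np.issubdtype(data.dtype, np.floating):
        vmin = float(np.nanmin(data))
        vmax = float(np.nanmax(data))
        span = vmax - vmin if vmax > vmin else 1.0
        img = np.round((data - vmin) / span * 65535).astype(np.uint16)
        meta["scale"] = {"vmin": vmin, "vmax": vmax}
    else:
        img = data.astype(np.uint16)
    iio.imwrite(path, img, extension=".png")
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_raster(path) -> Raster:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    img = iio.imread(path)
    dtype = meta.get("dtype", "uint8")
    if dtype == "bool":
        data = img > 127
    elif "scale" in meta:
        s = meta["scale"]
        data = img.astype(float) / 65535 * (s["vmax"] - s["vmin"]) + s["vmin"]
    elif dtype == "uint8":
        data = img.astype(np.uint8)
    else:
        data = img.astype(dtype)
    return Raster(
        data=data,
        origin_x=meta["origin_x"],
        origin_y=meta["origin_y"],
        pixel_size=meta["pixel_size"],
    )


def write_blocks_geojson(path, blocks) -> None:
    """``blocks`` is a sequence of (block_id, shapely Polygon) pairs."""
    features = [
        {
            "type": "Feature",
            "properties": {"block_id": bid},
            "geometry": mapping(poly),
        }
        for bid, poly in blocks
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_blocks_geojson(path) -> list:
    fc = json.loads(Path(path).read_text())
    return [
        (f["properties"]["block_id"], shape(f["geometry"])) for f in fc["features"]
    ]


def write_grid_counts(path, counts) -> None:
    pd.DataFrame({"x": counts.x, "y": counts.y, "count": counts.count}).to_csv(
        path, index=False
    )


def read_grid_counts(path, cell_size: float | None = None, block_id: str | None = None):
    from .gridding import GridCounts

    df = pd.read_csv(path)
    for col in ("x", "y", "count"):
        if col not in df.columns:
            raise ValueError(f"grid-count CSV must have columns x,y,count; missing {col!r}")
    if cell_size is None:
        # infer from the coordinate lattice if possible
        ux = np.unique(df["x"].to_numpy())
        cell_size = float(np.min(np.diff(ux))) if ux.size > 1 else 1.0
    return GridCounts(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        count=df["count"].to_numpy(float),
        cell_size=cell_size,
        block_id=block_id or "",
    )
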
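"""Partition blocks into square cells and count damaged pixels per cell.

The resulting ``x,y,count`` records (cell centroids in planar meters) are
the exchange format consumed by both the semivariogram and the SADIE
stages.  Counting follows a pixel-center containment rule so that cell
counts conserve the block-wide damaged-pixel total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .rasters import Raster
from .synthetic import GridSpec


@dataclass
class GridCounts:
    """Per-cell damaged-pixel counts at cell centroids."""

    x: np.ndarray
    y: np.ndarray
    count: np.ndarray
    cell_size: float
    block_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if not (self.x.shape == self.y.shape == self.count.shape):
            raise ValueError("x, y, count must have identical shapes")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_units(self) -> int:
        return self.x.size

    @property
    def total(self) -> float:
        return float(self.count.sum())

    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class BlockGrid:
    """A cell lattice covering one block, with inactive cells flagged.

    ``active`` is True for cells that overlap the block polygon with positive
    area; only active cells appear in the emitted counts.
    """

    spec: GridSpec
    active: np.ndarray
    block: Polygon
    block_id: str = ""

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def make_grid(block: Polygon, cell_size: float = 54.0, block_id: str = "") -> BlockGrid:
    """Minimal lattice of ``cell_size`` squares covering the block's bbox,
    dropping cells that do not overlap the polygon."""
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    if block.is_empty or block.area == 0:
        raise ValueError("degenerate (empty or zero-area) block polygon")
    minx, miny, maxx, maxy = block.bounds
    n_cols = int(np.ceil((maxx - minx) / cell_size - 1e-12))
    n_rows = int(np.ceil((maxy - miny) / cell_size - 1e-12))
    spec = GridSpec(
        n_rows=max(n_rows, 1),
        n_cols=max(n_cols, 1),
        cell_size=cell_size,
        origin_x=minx,
        origin_y=miny,
    )
    active = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            cell = box(
                minx + c * cell_size,
                miny + r * cell_size,
                minx + (c + 1) * cell_size,
                miny + (r + 1) * cell_size,
            )
            if cell.intersection(block).area > 0:
                active[r, c] = True
    return BlockGrid(spec=spec, active=active, block=block, block_id=block_id)


def count_damage_per_cell(damage: Raster, grid: BlockGrid) -> GridCounts:
    """Count damaged pixels (mask True) per active cell of a block grid.

    A pixel belongs to the cell containing its center; centers exactly on a
    shared cell edge go to the cell with the smaller (row, col).  Only pixels
    inside (or on the boundary of) the block polygon are counted, so the cell
    totals conserve the in-block damaged-pixel count exactly.
    """
    mask = np.asarray(damage.data, dtype=bool)
    spec = grid.spec
    gx, gy = damage.pixel_centers()
    tx = (gx - spec.origin_x) / spec.cell_size
    ty = (gy - spec.origin_y) / spec.cell_size
    col = np.floor(tx).astype(int)
    row = np.floor(ty).astype(int)
    # edge ties toward the smaller index
    col = np.where((tx == col) & (col > 0), col - 1, col)
    row = np.where((ty == row) & (row > 0), row - 1, row)

    inside_lattice = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    if not inside_lattice.any():
        raise ValueError(
            "raster extent does not overlap the block grid "
            f"(raster origin ({damage.origin_x}, {damage.origin_y}), "
            f"grid origin ({spec.origin_x}, {spec.origin_y}))"
        )
    in_block = shapely.intersects_xy(grid.block, gx, gy)
    keep = inside_lattice & in_block & mask
    flat = row[keep] * spec.n_cols + col[keep]
    counts = np.bincount(flat, minlength=spec.n_cells).reshape(spec.n_rows, spec.n_cols)

    centroids = spec.centroids().reshape(spec.n_rows, spec.n_cols, 2)
    act = grid.active
    return GridCounts(
        x=centroids[act][:, 0],
        y=centroids[act][:, 1],
        count=counts[act].astype(float),
        cell_size=spec.cell_size,
        block_id=grid.block_id,
    )
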
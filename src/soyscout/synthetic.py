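"""Synthetic defoliation scenes with known, controllable spatial structure.

This module stands in for field imagery: it draws stationary Gaussian random
fields with a requested variogram on a cell lattice, renders them as
vegetation/soil RGB scenes with per-pixel ground truth, and emits
before/during/after NIR+Red reflectance triplets whose NDVI drops in damaged
areas and recovers where crops regrow.  Every downstream stage of the
pipeline (defoliation mapping, gridding, geostatistics, SADIE, NDVI change
detection) can therefore be exercised against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.random import Generator, default_rng
from shapely.geometry import Polygon, box

from .models import MODELS, correlation


def _as_rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


@dataclass(frozen=True)
class VariogramParams:
    """Nugget/partial-sill/range description of a spatial covariance.

    ``nugget`` is the micro-scale (white-noise) variance, ``partial_sill``
    the spatially structured variance and ``range_eff`` the effective range
    in meters (lag at which the structured correlation has essentially
    vanished).  Total sill is ``nugget + partial_sill``.
    """

    model: str
    nugget: float
    partial_sill: float
    range_eff: float

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.nugget + self.partial_sill <= 0:
            raise ValueError("nugget + partial_sill must be > 0")
        if self.range_eff <= 0:
            raise ValueError("range_eff must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice of square cells in planar meter coordinates.

    The centroid of cell (r, c) is origin + ((c + 0.5), (r + 0.5)) * cell_size,
    with the y axis increasing with the row index.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 54.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be positive")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centroid (x, y), row-major order."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xx = self.origin_x + (cols + 0.5) * self.cell_size
        yy = self.origin_y + (rows + 0.5) * self.cell_size
        gx, gy = np.meshgrid(xx, yy)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def polygon(self) -> Polygon:
        return box(*self.extent())


class GaussianRandomField:
    """Stationary GRF sampler on the centroids of a :class:`GridSpec`.

    The covariance between cells i, j is
    ``partial_sill * rho(|x_i - x_j|) + nugget * 1[i == j]`` and sampling is
    by dense Cholesky of that matrix.  Building the factor is the expensive
    step; the object caches it so many seeds can be drawn cheaply.
    """

    def __init__(self, params: VariogramParams, grid: GridSpec, jitter: float = 1e-10):
        self.params = params
        self.grid = grid
        xy = grid.centroids()
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        cov = params.partial_sill * correlation(params.model, d, params.range_eff)
        cov[np.diag_indices_from(cov)] = params.sill
        try:
            self._chol = np.linalg.cholesky(cov + jitter * params.sill * np.eye(len(cov)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance not positive definite for "
                f"model={params.model!r}, range_eff={params.range_eff}, "
                f"grid={grid.n_rows}x{grid.n_cols} @ {grid.cell_size} m; "
                "the requested range is degenerate for this lattice"
            ) from exc

    def sample(self, seed=None) -> np.ndarray:
        """One zero-mean field of shape (n_rows, n_cols), variance = sill."""
        rng = _as_rng(seed)
        z = rng.standard_normal(self.grid.n_cells)
        return (self._chol @ z).reshape(self.grid.n_rows, self.grid.n_cols)


def generate_damage_field(
    params: VariogramParams,
    grid: GridSpec,
    seed=None,
    *,
    low: float = 0.2,
    high: float = 1.0,
    transform: str = "cdf",
) -> np.ndarray:
    """Continuous per-cell damage intensity with the requested variogram.

    A unit-variance GRF is pushed through the standard normal CDF (uniform
    marginal) and affinely mapped to ``[low, high]``; this keeps the marginal
    damage level controllable independently of the variogram shape.  With
    ``transform="none"`` the raw Gaussian field (variance = total sill) is
    returned, which is what variogram-recovery experiments consume.
    """
    from scipy.stats import norm

    if transform not in ("cdf", "none"):
        raise ValueError(f"transform must be 'cdf' or 'none', got {transform!r}")
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError("need 0 <= low <= high <= 1")
    raw = GaussianRandomField(params, grid).sample(seed)
    if transform == "none":
        return raw
    u = norm.cdf(raw / np.sqrt(params.sill))
    return low + (high - low) * u


# ---------------------------------------------------------------------------
# RGB rendering


@dataclass(frozen=True)
class RenderConfig:
    """How a damage field is rasterized into an RGB scene.

    ``px_per_cell`` is the pixel count per cell side; vegetation/soil base
    colors are jittered by +/- ``jitter`` per 8-bit channel.
    """

    px_per_cell: int = 20
    veg_rgb: tuple[int, int, int] = (60, 140, 60)
    soil_rgb: tuple[int, int, int] = (150, 120, 90)
    jitter: int = 10

    def __post_init__(self):
        if self.px_per_cell < 1:
            raise ValueError("px_per_cell must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class DamageScene:
    """Rendered scene plus exact ground truth.

    ``truth_mask`` is True where a pixel was rendered as bare soil
    (defoliated); ``realized_fraction`` stores the per-cell defoliated pixel
    fraction actually drawn, which is what truth-recovery tests compare
    against.
    """

    field: np.ndarray            # (n_rows, n_cols) damage intensity in [0, 1]
    rgb: np.ndarray              # (H, W, 3) uint8
    truth_mask: np.ndarray       # (H, W) bool, True = defoliated
    realized_fraction: np.ndarray  # (n_rows, n_cols)
    grid: GridSpec
    pixel_size: float            # meters per pixel side
    blocks: list = dc_field(default_factory=list)  # (block_id, Polygon) pairs

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2


def default_blocks(grid: GridSpec, n_block_rows: int = 1, n_block_cols: int = 1) -> list:
    """Tile the grid extent into a rectangular layout of named blocks."""
    x0, y0, x1, y1 = grid.extent()
    bw = (x1 - x0) / n_block_cols
    bh = (y1 - y0) / n_block_rows
    blocks = []
    k = 1
    for br in range(n_block_rows):
        for bc in range(n_block_cols):
            poly = box(x0 + bc * bw, y0 + br * bh, x0 + (bc + 1) * bw, y0 + (br + 1) * bh)
            blocks.append((f"block_{k}", poly))
            k += 1
    return blocks


def render_scene(
    field: np.ndarray,
    grid: GridSpec,
    cfg: RenderConfig | None = None,
    seed=None,
    blocks: list | None = None,
) -> DamageScene:
    """Render a damage field: each pixel is soil with probability equal to
    its cell's damage intensity, vegetation-green otherwise."""
    cfg = cfg or RenderConfig()
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"field shape {field.shape} != grid {grid.n_rows}x{grid.n_cols}")
    if field.min() < 0 or field.max() > 1:
        raise ValueError("field values must lie in [0, 1]")
    rng = _as_rng(seed)
    k = cfg.px_per_cell
    p = np.repeat(np.repeat(field, k, axis=0), k, axis=1)
    truth = rng.random(p.shape) < p
    veg = np.array(cfg.veg_rgb, dtype=np.int16)
    soil = np.array(cfg.soil_rgb, dtype=np.int16)
    rgb = np.where(truth[..., None], soil, veg)
    if cfg.jitter > 0:
        rgb = rgb + rng.integers(-cfg.jitter, cfg.jitter + 1, size=rgb.shape, dtype=np.int16)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    realized = truth.reshape(grid.n_rows, k, grid.n_cols, k).mean(axis=(1, 3))
    if blocks is None:
        blocks = default_blocks(grid)
    return DamageScene(
        field=field,
        rgb=rgb,
        truth_mask=truth,
        realized_fraction=realized,
        grid=grid,
        pixel_size=grid.cell_size / k,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# NDVI triplets


@dataclass(frozen=True)
class NdviSimConfig:
    """Targets for the before/during/after reflectance simulator.

    NDVI targets must lie in (-1, 1); ``brightness`` is NIR + Red, held
    constant so each NDVI target maps to a unique reflectance pair.
    ``noise_sd`` is additive Gaussian noise on each reflectance band,
    clipped so values stay in [0, 1].
    """

    healthy_ndvi: float = 0.8
    damaged_ndvi: float = 0.2
    regrowth_fraction: float = 0.5
    noise_sd: float = 0.02
    brightness: float = 0.6

    def __post_init__(self):
        for name in ("healthy_ndvi", "damaged_ndvi"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1), got {v}")
        if not 0.0 <= self.regrowth_fraction <= 1.0:
            raise ValueError("regrowth_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.brightness <= 1.0:
            raise ValueError("brightness must be in (0, 1]")


@dataclass
class NdviTriplet:
    """NIR/Red reflectance pairs for the epochs before, during, after an
    outbreak, plus the damage and regrowth truth masks used to build them."""

    nir: dict  # epoch -> (H, W) reflectance in [0, 1]
    red: dict
    damaged_mask: np.ndarray
    regrown_mask: np.ndarray

    EPOCHS = ("before", "during", "after")


def _reflectance_pair(ndvi: float, brightness: float) -> tuple[float, float]:
    nir = brightness * (1.0 + ndvi) / 2.0
    red = brightness * (1.0 - ndvi) / 2.0
    return nir, red


def generate_ndvi_triplet(
    damaged_mask: np.ndarray,
    cfg: NdviSimConfig | None = None,
    seed=None,
) -> NdviTriplet:
    """Simulate an outbreak in reflectance space.

    Before: healthy everywhere.  During: damaged pixels take the low-NDVI
    reflectances.  After: an exact ``regrowth_fraction`` share of the damaged
    pixels (chosen uniformly at random) reverts to healthy; the rest stay
    damaged.
    """
    cfg = cfg or NdviSimConfig()
    damaged_mask = np.asarray(damaged_mask, dtype=bool)
    rng = _as_rng(seed)

    dmg_idx = np.flatnonzero(damaged_mask)
    n_regrow = int(round(cfg.regrowth_fraction * dmg_idx.size))
    regrow_idx = rng.permutation(dmg_idx)[:n_regrow]
    regrown = np.zeros(damaged_mask.shape, dtype=bool)
    regrown.ravel()[regrow_idx] = True

    nir_h, red_h = _reflectance_pair(cfg.healthy_ndvi, cfg.brightness)
    nir_d, red_d = _reflectance_pair(cfg.damaged_ndvi, cfg.brightness)

    nir, red = {}, {}
    shape = damaged_mask.shape
    epoch_damaged = {
        "before": np.zeros(shape, dtype=bool),
        "during": damaged_mask,
        "after": damaged_mask & ~regrown,
    }
    for epoch in NdviTriplet.EPOCHS:
        dm = epoch_damaged[epoch]
        n = np.where(dm, nir_d, nir_h)
        r = np.where(dm, red_d, red_h)
        if cfg.noise_sd > 0:
            n = n + rng.normal(0.0, cfg.noise_sd, shape)
            r = r + rng.normal(0.0, cfg.noise_sd, shape)
        nir[epoch] = np.clip(n, 0.0, 1.0)
        red[epoch] = np.clip(r, 0.0, 1.0)
    return NdviTriplet(nir=nir, red=red, damaged_mask=damaged_mask, regrown_mask=regrown)
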
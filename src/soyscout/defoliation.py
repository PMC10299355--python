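"""Defoliation quantification from RGB rasters.

Foliage is identified by an excess-green index threshold (ExG = 2G - R - B),
calibrated against the green fraction of an undamaged reference area:
defoliation percent is the relative reduction in green fraction.  Ground
damage categories follow the standard five-band scouting scale: severe
(75-100%), high (50-75%), medium (25-50%), low (1-25%), none (0%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

CATEGORIES = ("severe", "high", "medium", "low", "none")


@dataclass(frozen=True)
class GreenConfig:
    """Green-pixel classifier settings.

    ``method="exg"`` thresholds the excess-green index at ``tau`` (8-bit
    units); ``method="hsv"`` accepts pixels with hue inside ``hue_range``
    (fractions of the color wheel) and saturation above ``min_saturation``.
    """

    method: str = "exg"
    tau: float = 20.0
    hue_range: tuple[float, float] = (0.17, 0.45)
    min_saturation: float = 0.15

    def __post_init__(self):
        if self.method not in ("exg", "hsv"):
            raise ValueError(f"method must be 'exg' or 'hsv', got {self.method!r}")


@dataclass
class DefoliationReport:
    block_id: str
    green_pixels: int
    total_pixels: int
    green_fraction: float
    defoliation_pct: float
    planted_area_ha: float
    defoliated_area_ha: float
    category: str


def _rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    arr = rgb.astype(float) / 255.0
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    diff = mx - mn
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    h = np.zeros_like(mx)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / diff, 6.0)
        hg = (b - r) / diff + 2.0
        hb = (r - g) / diff + 4.0
    h = np.where(mx == r, hr, np.where(mx == g, hg, hb)) / 6.0
    h = np.where(diff == 0, 0.0, h)
    s = np.where(mx == 0, 0.0, diff / np.where(mx == 0, 1.0, mx))
    return np.stack([h, s, mx], axis=-1)


def classify_green(rgb: np.ndarray, cfg: GreenConfig | None = None,
                   block_mask: np.ndarray | None = None):
    """Binary green-vegetation mask of an 8-bit RGB raster.

    Returns ``(mask, count)``; pixels outside ``block_mask`` (if given) are
    always False and excluded from the count.
    """
    cfg = cfg or GreenConfig()
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {rgb.shape}")
    if cfg.method == "exg":
        x = rgb.astype(np.int32)
        exg = 2 * x[..., 1] - x[..., 0] - x[..., 2]
        mask = exg > cfg.tau
    else:
        hsv = _rgb_to_hsv(rgb)
        lo, hi = cfg.hue_range
        mask = (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi) & (hsv[..., 1] >= cfg.min_saturation)
    if block_mask is not None:
        mask = mask & np.asarray(block_mask, dtype=bool)
    return mask, int(mask.sum())


def polygon_pixel_mask(poly, shape, origin_x: float, origin_y: float,
                       pixel_size: float) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside (or on) a polygon."""
    h, w = shape[:2]
    xs = origin_x + (np.arange(w) + 0.5) * pixel_size
    ys = origin_y + (np.arange(h) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    return shapely.intersects_xy(poly, gx, gy)


def estimate_block_defoliation(
    green_mask: np.ndarray,
    block_mask: np.ndarray | None,
    reference_green_fraction: float,
    *,
    block_id: str = "",
    pixel_area_m2: float = 0.02,
) -> DefoliationReport:
    """Per-block defoliation from a green mask and a reference calibration.

    defoliation_pct = 100 * (1 - green_fraction / reference), clipped to
    [0, 100].  ``block_mask`` restricts the raster to the block footprint
    (None = whole raster).  Planted area is the block pixel count times
    ``pixel_area_m2``; defoliated area scales it by the defoliation percent.
    """
    if reference_green_fraction <= 0:
        raise ValueError(
            "reference green fraction must be > 0 (an all-bare reference "
            "cannot calibrate defoliation)"
        )
    green_mask = np.asarray(green_mask, dtype=bool)
    if block_mask is None:
        total = green_mask.size
        green = int(green_mask.sum())
    else:
        block_mask = np.asarray(block_mask, dtype=bool)
        total = int(block_mask.sum())
        green = int((green_mask & block_mask).sum())
    if total == 0:
        raise ValueError(f"block {block_id!r} contains no pixels")
    gf = green / total
    pct = float(np.clip(100.0 * (1.0 - gf / reference_green_fraction), 0.0, 100.0))
    planted_ha = total * pixel_area_m2 / 1e4
    return DefoliationReport(
        block_id=block_id,
        green_pixels=green,
        total_pixels=total,
        green_fraction=gf,
        defoliation_pct=pct,
        planted_area_ha=planted_ha,
        defoliated_area_ha=planted_ha * pct / 100.0,
        category=categorize_damage(pct),
    )


def categorize_damage(pct: float) -> str:
    """Five-band damage category for a defoliation percentage.

    Band edges are half-open, closed at the lower edge of the higher band:
    [75, 100] severe, [50, 75) high, [25, 50) medium, (0, 25) low, 0 none.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"defoliation percent must be in [0, 100], got {pct}")
    if pct >= 75.0:
        return "severe"
    if pct >= 50.0:
        return "high"
    if pct >= 25.0:
        return "medium"
    if pct > 0.0:
        return "low"
    return "none"


@dataclass
class StudySummary:
    planted_area_ha: float
    defoliated_area_ha: float
    defoliation_pct: float
    category_shares: dict  # category -> percent of blocks


def overall_defoliation_pct(defoliated_area_ha: float, planted_area_ha: float) -> float:
    """Area-weighted study-wide defoliation percent."""
    if planted_area_ha <= 0:
        raise ValueError("planted area must be > 0")
    return 100.0 * defoliated_area_ha / planted_area_ha


def aggregate_reports(reports) -> StudySummary:
    """Study-wide totals: overall percent is area weighted; category shares
    are percent of blocks per category and sum to 100."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one block report")
    planted = sum(r.planted_area_ha for r in reports)
    defoliated = sum(r.defoliated_area_ha for r in reports)
    shares = {c: 0.0 for c in CATEGORIES}
    for r in reports:
        shares[r.category] += 1.0
    n = len(reports)
    shares = {c: 100.0 * v / n for c, v in shares.items()}
    return StudySummary(
        planted_area_ha=planted,
        defoliated_area_ha=defoliated,
        defoliation_pct=overall_defoliation_pct(defoliated, planted),
        category_shares=shares,
    )
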
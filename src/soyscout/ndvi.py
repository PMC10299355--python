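"""NDVI computation and before/during/after change detection.

NDVI = (NIR - Red) / (NIR + Red) per pixel, in [-1, 1].  Damage is flagged
where NDVI drops by more than a threshold between the before and during
epochs; regrowth where it rises between during and after; the overlap map
marks areas both damaged and recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLD = 0.05


@dataclass
class NdviRaster:
    values: np.ndarray   # NDVI, nan where nodata
    nodata: np.ndarray   # bool, True where undefined (NIR + Red == 0)
    epoch: str = ""


@dataclass
class ChangeMap:
    delta: np.ndarray    # NDVI difference (loss or gain), nan where nodata
    mask: np.ndarray     # bool, delta > threshold
    threshold: float
    kind: str            # "loss" or "gain"

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())

    def summary(self) -> dict:
        vals = self.delta[self.mask]
        return {
            "kind": self.kind,
            "threshold": self.threshold,
            "n_flagged": self.n_flagged,
            "min": float(vals.min()) if vals.size else None,
            "max": float(vals.max()) if vals.size else None,
        }


def compute_ndvi(nir: np.ndarray, red: np.ndarray, epoch: str = "") -> NdviRaster:
    """Pixelwise NDVI from reflectance rasters; NIR + Red = 0 is nodata."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError(f"NIR shape {nir.shape} != Red shape {red.shape}")
    if np.nanmin(nir) < 0 or np.nanmin(red) < 0:
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    nodata = ~(denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(nodata, np.nan, (nir - red) / np.where(nodata, 1.0, denom))
    return NdviRaster(values=values, nodata=nodata, epoch=epoch)


def _difference(a: NdviRaster, b: NdviRaster, threshold: float, kind: str) -> ChangeMap:
    if a.values.shape != b.values.shape:
        raise ValueError("epoch rasters must share dimensions")
    delta = a.values - b.values
    nodata = a.nodata | b.nodata
    delta = np.where(nodata, np.nan, delta)
    mask = np.where(nodata, False, delta > threshold)
    return ChangeMap(delta=delta, mask=mask, threshold=threshold, kind=kind)


def change_map(before: NdviRaster, during: NdviRaster,
               threshold: float = DEFAULT_THRESHOLD) -> ChangeMap:
    """NDVI loss (before - during) with a damage mask at ``loss > threshold``."""
    return _difference(before, during, threshold, kind="loss")


def regrowth_map(after: NdviRaster, during: NdviRaster,
                 threshold: float = DEFAULT_THRESHOLD) -> ChangeMap:
    """NDVI gain (after - during) with a regrowth mask at ``gain > threshold``."""
    return _difference(after, during, threshold, kind="gain")


def overlap_map(damage_mask: np.ndarray, regrowth_mask: np.ndarray) -> np.ndarray:
    """Pixels both damaged and regrown (logical AND)."""
    damage_mask = np.asarray(damage_mask, dtype=bool)
    regrowth_mask = np.asarray(regrowth_mask, dtype=bool)
    if damage_mask.shape != regrowth_mask.shape:
        raise ValueError("masks must share dimensions")
    return damage_mask & regrowth_mask
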
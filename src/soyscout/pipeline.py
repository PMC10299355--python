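"""End-to-end pipeline: simulate -> defoliate -> grid -> variogram/SADIE ->
NDVI -> economics, driven by one config with per-stage seeds and a
machine-readable run manifest.

Each stage writes its outputs under the run directory and records them (with
content hashes) in ``manifest.json``; a rerun with the same config is
byte-identical for every deterministic output.  Stages consume in-memory
state when run together and fall back to reading the files a previous run
left behind, so any suffix of the stage list can be re-executed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defoliation import (
    GreenConfig,
    aggregate_reports,
    classify_green,
    estimate_block_defoliation,
    polygon_pixel_mask,
)
from .economics import SurveyCostParams, breakeven, cost_profile
from .geostats import empirical_semivariogram, fit_all_models, select_best_model
from .gridding import count_damage_per_cell, make_grid
from .ndvi import change_map, compute_ndvi, overlap_map, regrowth_map
from .rasters import (
    Raster,
    read_blocks_geojson,
    read_grid_counts,
    read_raster,
    write_blocks_geojson,
    write_grid_counts,
    write_raster,
)
from .sadie import sadie_inference
from .synthetic import (
    GridSpec,
    NdviSimConfig,
    RenderConfig,
    VariogramParams,
    default_blocks,
    generate_damage_field,
    generate_ndvi_triplet,
    render_scene,
)

STAGES = ("simulate", "defoliate", "grid", "variogram", "sadie", "ndvi", "econ")


def _strict(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys under {path!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateConfig:
    model: str = "exponential"
    nugget: float = 0.2
    partial_sill: float = 0.8
    range_eff: float = 108.0
    n_rows: int = 16
    n_cols: int = 16
    cell_size: float = 27.0
    px_per_cell: int = 8
    low: float = 0.2
    high: float = 1.0
    jitter: int = 10
    n_block_rows: int = 2
    n_block_cols: int = 2
    healthy_ndvi: float = 0.8
    damaged_ndvi: float = 0.2
    regrowth_fraction: float = 0.5
    noise_sd: float = 0.02


@dataclass(frozen=True)
class DefoliateConfig:
    tau: float = 20.0
    reference_block: str | None = None  # default: greenest block


@dataclass(frozen=True)
class GridStageConfig:
    cell_size: float = 27.0
    exclude_above_pct: float = 95.0  # blocks beyond this defoliation are skipped


@dataclass(frozen=True)
class VariogramStageConfig:
    n_bins: int = 8
    max_lag: float | None = None


@dataclass(frozen=True)
class SadieStageConfig:
    k: int = 199


@dataclass(frozen=True)
class NdviStageConfig:
    threshold: float = 0.05


@dataclass(frozen=True)
class EconStageConfig:
    n_max: int = 60
    params: dict = field(default_factory=dict)  # SurveyCostParams overrides

    def cost_params(self) -> SurveyCostParams:
        return _strict(SurveyCostParams, dict(self.params), "econ.params")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    stages: tuple = STAGES
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    defoliate: DefoliateConfig = field(default_factory=DefoliateConfig)
    grid: GridStageConfig = field(default_factory=GridStageConfig)
    variogram: VariogramStageConfig = field(default_factory=VariogramStageConfig)
    sadie: SadieStageConfig = field(default_factory=SadieStageConfig)
    ndvi: NdviStageConfig = field(default_factory=NdviStageConfig)
    econ: EconStageConfig = field(default_factory=EconStageConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        sub = {
            "simulate": SimulateConfig,
            "defoliate": DefoliateConfig,
            "grid": GridStageConfig,
            "variogram": VariogramStageConfig,
            "sadie": SadieStageConfig,
            "ndvi": NdviStageConfig,
            "econ": EconStageConfig,
        }
        kwargs = {}
        for key, val in data.items():
            if key in sub:
                kwargs[key] = _strict(sub[key], dict(val), key)
            elif key == "stages":
                bad = set(val) - set(STAGES)
                if bad:
                    raise ValueError(f"unknown stages: {sorted(bad)}")
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Executes enabled stages in dependency order against one directory."""

    def __init__(self, config: RunConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.manifest = {
            "package": "soyscout",
            "version": __version__,
            "seed": config.seed,
            "stages": {},
        }

    # -- helpers ---------------------------------------------------------

    def _record(self, stage: str, outputs: list[Path], seed, t0: float):
        self.manifest["stages"][stage] = {
            "seed": seed,
            "outputs": [str(p.relative_to(self.outdir)) for p in outputs],
            "sha256": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "seconds": round(time.time() - t0, 3),
        }

    def _need_scene(self):
        if "rgb" in self.state:
            return
        rgb_path = self.outdir / "scene_rgb.png"
        if not rgb_path.exists():
            raise FileNotFoundError(
                "stage requires the simulated scene; run the 'simulate' stage "
                f"first or place scene files in {self.outdir}"
            )
        self.state["rgb"] = read_raster(rgb_path)
        self.state["truth"] = read_raster(self.outdir / "truth_mask.png")
        self.state["blocks"] = read_blocks_geojson(self.outdir / "blocks.geojson")

    # -- stages ----------------------------------------------------------

    def stage_simulate(self):
        cfg = self.config.simulate
        seed = self.config.seed
        params = VariogramParams(cfg.model, cfg.nugget, cfg.partial_sill, cfg.range_eff)
        grid = GridSpec(n_rows=cfg.n_rows, n_cols=cfg.n_cols, cell_size=cfg.cell_size)
        fld = generate_damage_field(params, grid, seed, low=cfg.low, high=cfg.high)
        blocks = default_blocks(grid, cfg.n_block_rows, cfg.n_block_cols)
        scene = render_scene(
            fld, grid, RenderConfig(px_per_cell=cfg.px_per_cell, jitter=cfg.jitter),
            seed=seed + 1, blocks=blocks,
        )
        triplet = generate_ndvi_triplet(
            scene.truth_mask,
            NdviSimConfig(
                healthy_ndvi=cfg.healthy_ndvi,
                damaged_ndvi=cfg.damaged_ndvi,
                regrowth_fraction=cfg.regrowth_fraction,
                noise_sd=cfg.noise_sd,
            ),
            seed=seed + 2,
        )
        ps = scene.pixel_size
        rgb = Raster(scene.rgb, pixel_size=ps)
        truth = Raster(scene.truth_mask, pixel_size=ps)
        outputs = []
        for name, raster in [("scene_rgb", rgb), ("truth_mask", truth)]:
            p = self.outdir / f"{name}.png"
            write_raster(p, raster)
            outputs.extend([p, p.with_suffix(".png.json")])
        for epoch in ("before", "during", "after"):
            for band, stack in [("nir", triplet.nir), ("red", triplet.red)]:
                p = self.outdir / f"ndvi_{epoch}_{band}.png"
                write_raster(p, Raster(stack[epoch], pixel_size=ps))
                outputs.extend([p, p.with_suffix(".png.json")])
        bp = self.outdir / "blocks.geojson"
        write_blocks_geojson(bp, blocks)
        outputs.append(bp)
        self.state.update(
            {"scene": scene, "rgb": rgb, "truth": truth, "blocks": blocks,
             "triplet": triplet}
        )
        return outputs, seed

    def stage_defoliate(self):
        cfg = self.config.defoliate
        self._need_scene()
        rgb: Raster = self.state["rgb"]
        blocks = self.state["blocks"]
        green, _ = classify_green(rgb.data, GreenConfig(tau=cfg.tau))
        block_masks = {
            bid: polygon_pixel_mask(poly, rgb.shape, rgb.origin_x, rgb.origin_y,
                                    rgb.pixel_size)
            for bid, poly in blocks
        }
        gfs = {
            bid: (green & bm).sum() / max(bm.sum(), 1)
            for bid, bm in block_masks.items()
        }
        ref_id = cfg.reference_block or max(gfs, key=gfs.get)
        if gfs[ref_id] <= 0:
            raise ValueError(f"reference block {ref_id!r} has zero green fraction")
        reports = [
            estimate_block_defoliation(
                green, block_masks[bid], gfs[ref_id], block_id=bid,
                pixel_area_m2=rgb.pixel_size**2,
            )
            for bid, _ in blocks
        ]
        summary = aggregate_reports(reports)
        df = pd.DataFrame(
            [
                {
                    "block_id": r.block_id,
                    "green_pixels": r.green_pixels,
                    "total_pixels": r.total_pixels,
                    "defoliation_pct": r.defoliation_pct,
                    "category": r.category,
                    "area_ha": r.planted_area_ha,
                }
                for r in reports
            ]
        )
        csv_path = self.outdir / "defoliation.csv"
        df.to_csv(csv_path, index=False)
        json_path = self.outdir / "defoliation_summary.json"
        json_path.write_text(
            json.dumps(
                {
                    "planted_area_ha": summary.planted_area_ha,
                    "defoliated_area_ha": summary.defoliated_area_ha,
                    "defoliation_pct": summary.defoliation_pct,
                    "category_shares": summary.category_shares,
                    "reference_block": ref_id,
                },
                indent=1,
            )
        )
        dmg_path = self.outdir / "damage_mask.png"
        damage = Raster(~green, rgb.origin_x, rgb.origin_y, rgb.pixel_size)
        write_raster(dmg_path, damage)
        self.state.update({"reports": reports, "damage": damage})
        return [csv_path, json_path, dmg_path, dmg_path.with_suffix(".png.json")], None

    def _block_defoliation_pct(self) -> dict:
        if "reports" in self.state:
            return {r.block_id: r.defoliation_pct for r in self.state["reports"]}
        path = self.outdir / "defoliation.csv"
        if path.exists():
            df = pd.read_csv(path)
            return dict(zip(df["block_id"], df["defoliation_pct"]))
        return {}

    def stage_grid(self):
        cfg = self.config.grid
        self._need_scene()
        if "damage" not in self.state:
            path = self.outdir / "damage_mask.png"
            if not path.exists():
                raise FileNotFoundError("grid stage requires the 'defoliate' stage outputs")
            self.state["damage"] = read_raster(path)
        damage: Raster = self.state["damage"]
        pct = self._block_defoliation_pct()
        outputs = []
        counts_by_block = {}
        for bid, poly in self.state["blocks"]:
            if pct.get(bid, 0.0) > cfg.exclude_above_pct:
                continue  # near-total loss: no spatial pattern left to analyze
            bg = make_grid(poly, cfg.cell_size, block_id=bid)
            gc = count_damage_per_cell(damage, bg)
            p = self.outdir / f"counts_{bid}.csv"
            write_grid_counts(p, gc)
            outputs.append(p)
            counts_by_block[bid] = gc
        self.state["counts"] = counts_by_block
        return outputs, None

    def _need_counts(self) -> dict:
        if "counts" not in self.state:
            files = sorted(self.outdir.glob("counts_*.csv"))
            if not files:
                raise FileNotFoundError("stage requires grid-count CSVs; run 'grid' first")
            self.state["counts"] = {
                p.stem.removeprefix("counts_"): read_grid_counts(p) for p in files
            }
        return self.state["counts"]

    def stage_variogram(self):
        cfg = self.config.variogram
        rows = []
        for bid, gc in self._need_counts().items():
            sv = empirical_semivariogram(gc, n_bins=cfg.n_bins, max_lag=cfg.max_lag)
            fit = select_best_model(fit_all_models(sv))
            rows.append(
                {
                    "block_id": bid,
                    "model": fit.model,
                    "nugget": fit.nugget,
                    "sill": fit.sill_total,
                    "dd_pct": fit.dd,
                    "dd_class": fit.dd_class,
                    "range_m": fit.range_eff,
                    "r2": fit.r2,
                    "rss": fit.rss,
                }
            )
        path = self.outdir / "variogram.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path], None

    def stage_sadie(self):
        cfg = self.config.sadie
        seed = self.config.seed + 10
        rows = []
        for bid, gc in self._need_counts().items():
            r = sadie_inference(gc, k=cfg.k, seed=seed)
            rows.append(
                {
                    "block_id": bid,
                    "d": r.d,
                    "ia": r.ia,
                    "pa": r.pa,
                    "vbar_j": r.vbar_j,
                    "vbar_i": r.vbar_i,
                    "p_vj": r.p_vj,
                    "p_vi": r.p_vi,
                }
            )
        path = self.outdir / "sadie.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path], seed

    def stage_ndvi(self):
        cfg = self.config.ndvi
        if "triplet" in self.state:
            tr = self.state["triplet"]
            nir = tr.nir
            red = tr.red
        else:
            nir, red = {}, {}
            for epoch in ("before", "during", "after"):
                np_ = self.outdir / f"ndvi_{epoch}_nir.png"
                rp = self.outdir / f"ndvi_{epoch}_red.png"
                if not np_.exists() or not rp.exists():
                    raise FileNotFoundError("ndvi stage requires the simulated triplet")
                nir[epoch] = read_raster(np_).data
                red[epoch] = read_raster(rp).data
        rasters = {e: compute_ndvi(nir[e], red[e], epoch=e) for e in ("before", "during", "after")}
        loss = change_map(rasters["before"], rasters["during"], cfg.threshold)
        gain = regrowth_map(rasters["after"], rasters["during"], cfg.threshold)
        overlap = overlap_map(loss.mask, gain.mask)
        path = self.outdir / "ndvi_summary.json"
        path.write_text(
            json.dumps(
                {
                    "loss": loss.summary(),
                    "gain": gain.summary(),
                    "overlap_pixels": int(overlap.sum()),
                },
                indent=1,
            )
        )
        return [path], None

    def stage_econ(self):
        cfg = self.config.econ
        params = cfg.cost_params()
        profile = cost_profile(params, cfg.n_max)
        csv_path = self.outdir / "economics.csv"
        profile.to_csv(csv_path, index=False)
        report = {
            mode: breakeven(params, mode, cfg.n_max).n_star for mode in ("time", "cost")
        }
        json_path = self.outdir / "breakeven.json"
        json_path.write_text(json.dumps(report, indent=1))
        return [csv_path, json_path], None

    # -- driver ----------------------------------------------------------

    def run(self) -> dict:
        handlers = {
            "simulate": self.stage_simulate,
            "defoliate": self.stage_defoliate,
            "grid": self.stage_grid,
            "variogram": self.stage_variogram,
            "sadie": self.stage_sadie,
            "ndvi": self.stage_ndvi,
            "econ": self.stage_econ,
        }
        for stage in STAGES:  # dependency order regardless of config order
            if stage not in self.config.stages:
                continue
            t0 = time.time()
            try:
                outputs, seed = handlers[stage]()
            except Exception:
                # drop partial outputs so a failed run leaves no half-written stage
                for p in self.outdir.glob("*"):
                    if p.name != "manifest.json" and stage in p.name:
                        p.unlink(missing_ok=True)
                raise
            self._record(stage, outputs, seed, t0)
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured stages and return the manifest."""
    return PipelineRun(config, outdir).run()
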
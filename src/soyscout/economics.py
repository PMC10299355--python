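"""Aerial-versus-ground survey time and cost models.

Aerial survey: one fixed pre-flight check plus a per-block flight time and a
per-block image-analysis time, billed at the expert fee plus the technology
(equipment/software rental) fee:

    C_aerial(N) = (T_UAS + T_analysis) * (F_expert + F_technology),
    T_UAS = t_preflight + t_flight * N,   T_analysis = t_analysis * N.

Ground survey: person-hours scale linearly at the observed per-block rate
(surveyor crew-hours divided by blocks covered), billed at the labor fee:

    C_ground(N) = F_labor * T_ground(N),  T_ground = rate * N.

Default parameter values reproduce the motivating field campaign: a 0.5 h
pre-flight check, 0.05 h flight and 0.0645 h analysis per block, USD 50/h
expert and USD 100/h technology fees, and a 19-surveyor crew that covered
45 blocks in 1.1 h each at USD 10/h.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SurveyCostParams:
    t_preflight: float = 0.5            # h, fixed per mission
    t_flight_per_block: float = 0.05    # h/block
    t_analysis_per_block: float = 0.0645  # h/block
    f_expert: float = 50.0              # USD/h
    f_technology: float = 100.0         # USD/h
    f_labor: float = 10.0               # USD/h per surveyor
    n_surveyors: int = 19
    ground_hours_per_surveyor: float = 1.1
    blocks_ground_surveyed: int = 45

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.blocks_ground_surveyed < 1:
            raise ValueError("blocks_ground_surveyed must be >= 1")

    @property
    def ground_person_hours_per_block(self) -> float:
        return self.n_surveyors * self.ground_hours_per_surveyor / self.blocks_ground_surveyed


@dataclass
class SurveyCost:
    total_usd: float
    per_block_usd: float
    total_hours: float  # aerial: wall-clock expert hours; ground: person-hours


def per_block_rate(total_hours: float, n_blocks: int, ndigits: int = 4) -> float:
    """Per-block rate from an observed (total hours, blocks) pair, rounded
    to the reporting precision (e.g. 2 h over 31 blocks -> 0.0645 h)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return round(total_hours / n_blocks, ndigits)


def aerial_cost(params: SurveyCostParams, n_blocks: int) -> SurveyCost:
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    hours = (
        params.t_preflight
        + (params.t_flight_per_block + params.t_analysis_per_block) * n_blocks
    )
    total = hours * (params.f_expert + params.f_technology)
    return SurveyCost(total_usd=total, per_block_usd=total / n_blocks, total_hours=hours)


def ground_cost(params: SurveyCostParams, n_blocks: int) -> SurveyCost:
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    person_hours = params.ground_person_hours_per_block * n_blocks
    total = params.f_labor * person_hours
    return SurveyCost(
        total_usd=total, per_block_usd=total / n_blocks, total_hours=person_hours
    )


@dataclass
class BreakevenResult:
    mode: str
    n_star: int | None           # smallest N with aerial <= ground, or None
    profile: pd.DataFrame        # N, aerial, ground, gap (aerial - ground)


def breakeven(params: SurveyCostParams, mode: str = "time",
              n_max: int = 100) -> BreakevenResult:
    """Smallest block count at which the aerial survey is no more expensive
    (``mode="cost"``, USD) or no slower (``mode="time"``, person-hours) than
    the ground survey; None if no crossing occurs up to ``n_max``."""
    if mode not in ("time", "cost"):
        raise ValueError(f"mode must be 'time' or 'cost', got {mode!r}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    ns = np.arange(1, n_max + 1)
    if mode == "time":
        aerial = np.array([aerial_cost(params, int(n)).total_hours for n in ns])
        ground = np.array([ground_cost(params, int(n)).total_hours for n in ns])
    else:
        aerial = np.array([aerial_cost(params, int(n)).total_usd for n in ns])
        ground = np.array([ground_cost(params, int(n)).total_usd for n in ns])
    gap = aerial - ground
    hit = np.flatnonzero(gap <= 0)
    n_star = int(ns[hit[0]]) if hit.size else None
    profile = pd.DataFrame({"n": ns, "aerial": aerial, "ground": ground, "gap": gap})
    return BreakevenResult(mode=mode, n_star=n_star, profile=profile)


def cost_profile(params: SurveyCostParams, n_max: int = 100) -> pd.DataFrame:
    """N versus aerial/ground hours and USD — the comparison-curve table."""
    rows = []
    for n in range(1, n_max + 1):
        a = aerial_cost(params, n)
        g = ground_cost(params, n)
        rows.append(
            {
                "n": n,
                "aerial_hours": a.total_hours,
                "ground_person_hours": g.total_hours,
                "aerial_usd": a.total_usd,
                "ground_usd": g.total_usd,
                "aerial_usd_per_block": a.per_block_usd,
                "ground_usd_per_block": g.per_block_usd,
            }
        )
    return pd.DataFrame(rows)
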
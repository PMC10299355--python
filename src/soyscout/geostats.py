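"""Semivariogram estimation, model fitting and the degree of spatial dependence.

The empirical semivariogram uses the Matheron moment estimator on binned
pair distances.  Exponential, spherical and Gaussian models (effective-range
parameterization, see :mod:`soyscout.models`) are fitted by bounded least
squares; the best model minimizes the residual sum of squares, with ties
broken by r^2.  The degree of spatial dependence

    DD = 100 * (sill_total - nugget) / sill_total

expresses the structured variance as a share of the total sill and is
classified weak (<= 25), moderate (25-76) or strong (>= 76).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .models import MODELS, variogram

_MODEL_ORDER = {m: i for i, m in enumerate(MODELS)}  # tie-break order


@dataclass
class Semivariogram:
    """Binned empirical semivariogram (empty bins already dropped)."""

    lags: np.ndarray      # bin midpoints, meters
    gamma: np.ndarray     # Matheron semivariance per bin
    n_pairs: np.ndarray   # pair count per bin
    max_lag: float
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.lags.size


@dataclass
class VariogramFit:
    model: str
    nugget: float
    sill_total: float
    range_eff: float
    r2: float
    rss: float
    converged: bool
    message: str = ""

    @property
    def partial_sill(self) -> float:
        return self.sill_total - self.nugget

    @property
    def dd(self) -> float:
        return degree_of_spatial_dependence(self.nugget, self.sill_total)[0]

    @property
    def dd_class(self) -> str:
        return degree_of_spatial_dependence(self.nugget, self.sill_total)[1]


def _xy_values(data, values):
    if values is None:  # GridCounts-like
        return data.xy(), np.asarray(data.count, dtype=float)
    return np.asarray(data, dtype=float), np.asarray(values, dtype=float)


def empirical_semivariogram(
    data,
    values=None,
    *,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> Semivariogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) per lag bin.

    ``data`` is either a GridCounts or an (N, 2) coordinate array with
    ``values`` given separately.  ``max_lag`` defaults to half the maximum
    inter-point distance; pairs beyond it are ignored and empty bins dropped.
    """
    xy, z = _xy_values(data, values)
    if xy.shape[0] < 2:
        raise ValueError("need at least two points")
    d = pdist(xy)
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all points coincident; semivariogram undefined")
    if max_lag is None:
        max_lag = dmax / 2.0
    sq = pdist(z[:, None], metric="sqeuclidean")

    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges[1:], right=True)  # bin 0..n_bins-1; > max_lag -> n_bins
    in_range = (idx < n_bins) & (d > 0)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    sums = np.bincount(idx[in_range], weights=sq[in_range], minlength=n_bins)
    nonempty = counts > 0
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    mids = (edges[:-1] + edges[1:])[nonempty] / 2.0
    return Semivariogram(
        lags=mids,
        gamma=gamma,
        n_pairs=counts[nonempty],
        max_lag=float(max_lag),
        bin_width=float(edges[1] - edges[0]),
    )


def fit_variogram_model(
    sv: Semivariogram,
    model: str,
    *,
    weight_by_pairs: bool = False,
) -> VariogramFit:
    """Bounded least-squares fit of one model to an empirical semivariogram.

    Parameters are (nugget C0 >= 0, partial sill C >= 0, effective range
    a > 0).  Several starting points are tried and the lowest-RSS solution
    kept.  r^2 = 1 - RSS/TSS with TSS about the mean semivariance; RSS is
    always the unweighted residual sum of squares (``weight_by_pairs`` only
    changes the objective, not the reported RSS).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if sv.n_bins < 4:
        raise ValueError(f"need >= 4 non-empty lag bins to fit, have {sv.n_bins}")
    h, g = sv.lags, sv.gamma
    w = np.sqrt(sv.n_pairs / sv.n_pairs.mean()) if weight_by_pairs else 1.0
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    def resid(p):
        return (variogram(model, h, p[0], p[1], p[2]) - g) * w

    best = None
    for a0 in (0.25 * hmax, 0.5 * hmax, hmax):
        for c0_frac in (0.0, 0.3):
            x0 = [c0_frac * gmax, max(gmax - c0_frac * gmax, 1e-9 * gmax), a0]
            try:
                res = least_squares(
                    resid, x0, bounds=([0.0, 0.0, 1e-9 * hmax], [np.inf, np.inf, 100.0 * hmax])
                )
            except Exception:  # pragma: no cover - scipy failure path
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return VariogramFit(model, np.nan, np.nan, np.nan, np.nan, np.inf,
                            converged=False, message="optimizer failed from all starts")
    c0, c, a = best.x
    rss = float(np.sum((variogram(model, h, c0, c, a) - g) ** 2))
    tss = float(np.sum((g - g.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if rss <= 1e-12 * gmax**2 else 0.0
    return VariogramFit(
        model=model,
        nugget=float(c0),
        sill_total=float(c0 + c),
        range_eff=float(a),
        r2=r2,
        rss=rss,
        converged=bool(best.success),
        message=str(best.message),
    )


def fit_all_models(sv: Semivariogram, **kwargs) -> list[VariogramFit]:
    return [fit_variogram_model(sv, m, **kwargs) for m in MODELS]


def select_best_model(fits) -> VariogramFit:
    """Lowest-RSS converged fit; relative-RSS ties (1e-9) broken by highest
    r^2, then by model order exponential < spherical < gaussian."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged variogram fits to select from")
    best_rss = min(f.rss for f in fits)
    tol = 1e-9 * max(best_rss, 1e-300)
    tied = [f for f in fits if f.rss - best_rss <= tol]
    return min(tied, key=lambda f: (-f.r2, _MODEL_ORDER[f.model]))


def degree_of_spatial_dependence(nugget: float, sill_total: float) -> tuple[float, str]:
    """DD percent and its dependence class from nugget and *total* sill.

    DD = 100 * (sill_total - nugget) / sill_total, i.e. the structured
    variance C = sill_total - C0 as a share of the total sill.  Classes:
    weak (DD <= 25), moderate (25 < DD < 76), strong (DD >= 76).
    """
    if sill_total <= 0:
        raise ValueError(f"total sill must be > 0, got {sill_total}")
    if nugget < 0 or nugget > sill_total:
        raise ValueError(
            f"nugget must lie in [0, sill_total], got nugget={nugget}, sill={sill_total}"
        )
    dd = 100.0 * (sill_total - nugget) / sill_total
    return dd, dd_class(dd)


def dd_class(dd: float) -> str:
    if dd <= 25.0:
        return "weak"
    if dd >= 76.0:
        return "strong"
    return "moderate"
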
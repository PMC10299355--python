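"""Canonical semivariogram model curves.

One parameterization is shared by the random-field generator and the fitting
routines so that recovery experiments are self-consistent.  ``range_eff`` is
always the *effective* range: the lag at which the model reaches ~95% of its
sill (exactly the sill for the spherical model).
"""

from __future__ import annotations

import numpy as np

MODELS = ("exponential", "spherical", "gaussian")


def correlation(model: str, h, range_eff: float):
    """Spatial correlation rho(h) of the structured component, in [0, 1].

    exponential: exp(-3h/a); gaussian: exp(-3(h/a)^2);
    spherical: 1 - 1.5(h/a) + 0.5(h/a)^3 for h <= a, else 0.
    """
    h = np.asarray(h, dtype=float)
    if range_eff <= 0:
        raise ValueError(f"range_eff must be > 0, got {range_eff}")
    u = h / range_eff
    if model == "exponential":
        return np.exp(-3.0 * u)
    if model == "gaussian":
        return np.exp(-3.0 * u**2)
    if model == "spherical":
        rho = 1.0 - 1.5 * u + 0.5 * u**3
        return np.where(u >= 1.0, 0.0, rho)
    raise ValueError(f"unknown variogram model {model!r}; expected one of {MODELS}")


def variogram(model: str, h, nugget: float, partial_sill: float, range_eff: float):
    """Model semivariance gamma(h) = C0 + C * (1 - rho(h)) for h > 0.

    The nugget applies for any strictly positive lag; gamma(0) = 0 by
    definition, but empirical estimates never include zero lags.
    """
    h = np.asarray(h, dtype=float)
    gamma = nugget + partial_sill * (1.0 - correlation(model, h, range_eff))
    return np.where(h <= 0, 0.0, gamma)
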
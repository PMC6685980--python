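"""Regulatory toxicity endpoints: LC(x,t), incipient LC, and MF(x,t).

LC(x,t) is the constant external concentration causing an x% reduction in
survival relative to the control at time t, defined by

    S(LC(x,t), t) = S(0, t) * (1 - x/100),

and is meaningful only under constant exposure.  MF(x,t) (the exposure
multiplication factor, LPx in EFSA terminology) is the factor applied to a
whole exposure profile that produces an x% survival reduction at time t.

Baseline convention for MF: the closed-form expressions for both models
correspond to an x% reduction relative to survival under the *unmultiplied
profile*, S(C_w, t); background mortality cancels either way.  A reduction
relative to the *control* S(0, t) is available via ``baseline="control"``.

Point endpoints are deterministic functions of a parameter vector;
``endpoint_distribution`` propagates a joint posterior sample through any
of them and summarises with 0.025 / 0.5 / 0.975 quantiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exposure import ExposureProfile, constant_profile
from .models import (
    GutsParams,
    ITParams,
    SDParams,
    exceedance_integral,
    max_damage,
    model_tag_of,
)

__all__ = [
    "EndpointEstimate",
    "lc_it",
    "lc_sd",
    "lc",
    "lc_incipient",
    "mf_it",
    "mf_sd",
    "mf",
    "endpoint_distribution",
]

logger = logging.getLogger(__name__)

_X_MIN, _X_MAX = 0.1, 99.9  # extreme-x guard: uncertainty explodes at 0/100


@dataclass(frozen=True)
class EndpointEstimate:
    """Posterior summary of one endpoint at one (x, t)."""

    endpoint_kind: str  # LC | MF | DRT
    x: float
    t: float
    median: float
    q025: float
    q975: float
    model_tag: str

    def __post_init__(self):
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles must be ordered q025 <= median <= q975")


def _check_x(x: float) -> float:
    """Clip x to [0.1, 99.9] with a warning; reject the exact extremes."""
    if not (0 < x < 100):
        raise ValueError("x must be strictly between 0 and 100")
    if x < _X_MIN or x > _X_MAX:
        logger.warning("x=%g clipped to [%g, %g]; endpoint uncertainty is maximal at extremes",
                       x, _X_MIN, _X_MAX)
        return float(np.clip(x, _X_MIN, _X_MAX))
    return x


# ---------------------------------------------------------------------------
# Lethal concentration
# ---------------------------------------------------------------------------

def lc_it(params: ITParams, x: float, t: float) -> float:
    """Closed-form GUTS-RED-IT lethal concentration.

    LC(x,t) = m_w / (1 - e^(-k_d t)) * (x / (100 - x))^(1/beta);
    increasing in x, decreasing in t, with incipient limit
    m_w (x/(100-x))^(1/beta).
    """
    x = _check_x(x)
    if t <= 0:
        raise ValueError("t must be > 0")
    return params.m_w / -math.expm1(-params.k_d * t) * (x / (100.0 - x)) ** (1.0 / params.beta)


def lc_sd(params: SDParams, x: float, t: float, conc_ceiling: float = 1e9) -> float:
    """GUTS-RED-SD lethal concentration by bracketed root-solve.

    Solves S_SD(C, t) = S_SD(0, t) (1 - x/100) for C; no explicit form
    exists because the threshold-crossing time t_z depends on C.  The root
    is bracketed above z with geometric expansion up to ``conc_ceiling``.
    """
    x = _check_x(x)
    if t <= 0:
        raise ValueError("t must be > 0")
    target = -math.log1p(-x / 100.0)  # required b_w * H(t)

    def g(C):
        H = exceedance_integral(constant_profile(C), params.k_d, params.z, [t])[0]
        return params.b_w * H - target

    lo = params.z if params.z > 0 else 0.0
    hi = max(2.0 * (params.z + 1.0), 1.0)
    while g(hi) < 0:
        hi *= 4.0
        if hi > conc_ceiling:
            raise RuntimeError(f"no LC bracket found below concentration ceiling {conc_ceiling}")
    # g(lo) <= -target < 0 (no exceedance at C <= z)
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-10)


def lc(params: GutsParams, x: float, t: float) -> float:
    """Dispatch LC(x,t) by parameter type."""
    if isinstance(params, SDParams):
        return lc_sd(params, x, t)
    return lc_it(params, x, t)


def lc_incipient(params: GutsParams, x: float) -> float:
    """Incipient lethal concentration, the t -> +inf limit of LC(x,t).

    z for SD (any x); m_w (x/(100-x))^(1/beta) for IT (m_w at x = 50).
    """
    x = _check_x(x)
    if isinstance(params, SDParams):
        return params.z
    return params.m_w * (x / (100.0 - x)) ** (1.0 / params.beta)


# ---------------------------------------------------------------------------
# Multiplication factor
# ---------------------------------------------------------------------------

def _check_mf_args(x, t, max_d):
    if t <= 0:
        raise ValueError("t must be > 0")
    if max_d <= 0:
        raise ValueError("MF is undefined for a profile with no exposure on [0, t]")


def mf_it(params: ITParams, profile: ExposureProfile, x: float, t: float,
          baseline: str = "profile") -> float:
    """GUTS-RED-IT multiplication factor, closed form.

    With M = max damage over [0, t] (one TK solve suffices):

    * baseline="profile":  MF^beta = (100 + x (M/m_w)^(-beta)) / (100 - x)
    * baseline="control":  MF = (x/(100-x))^(1/beta) * m_w / M
    """
    x = _check_x(x)
    M = max_damage(profile, params.k_d, t) if t > 0 else 0.0
    _check_mf_args(x, t, M)
    r = (M / params.m_w) ** params.beta
    if baseline == "profile":
        return ((100.0 + x / r) / (100.0 - x)) ** (1.0 / params.beta)
    if baseline == "control":
        return (x / (100.0 - x) / r) ** (1.0 / params.beta)
    raise ValueError("baseline must be 'profile' or 'control'")


def mf_sd(params: SDParams, profile: ExposureProfile, x: float, t: float,
          baseline: str = "profile", mf_ceiling: float = 1e9) -> float:
    """GUTS-RED-SD multiplication factor by bracketed root-solve.

    Solves S_SD(MF * C_w, t) = S_base(t) (1 - x/100) for MF, where the
    baseline is survival under the unmultiplied profile (default) or the
    control.  TK linearity (damage under MF*C_w equals MF times damage
    under C_w) reduces each evaluation to one exceedance integral with
    threshold z/MF:  H_MF(t) = MF * int max(D - z/MF, 0).
    """
    x = _check_x(x)
    M = max_damage(profile, params.k_d, t) if t > 0 else 0.0
    _check_mf_args(x, t, M)
    kd, z, bw = params.k_d, params.z, params.b_w

    def hazard_integral(mf):
        H = exceedance_integral(profile, kd, z / mf if z > 0 else 0.0, [t])[0]
        return bw * mf * H

    if baseline == "profile":
        offset = hazard_integral(1.0)
    elif baseline == "control":
        offset = 0.0
    else:
        raise ValueError("baseline must be 'profile' or 'control'")
    target = offset - math.log1p(-x / 100.0)

    def g(mf):
        return hazard_integral(mf) - target

    lo, hi = 1e-6, 2.0
    while g(hi) < 0:
        hi *= 4.0
        if hi > mf_ceiling:
            raise RuntimeError(f"no MF bracket found below ceiling {mf_ceiling}")
    while g(lo) > 0:
        lo /= 4.0
        if lo < 1e-12:
            raise RuntimeError("MF bracket collapsed at zero")
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-10)


def mf(params: GutsParams, profile: ExposureProfile, x: float, t: float,
       baseline: str = "profile") -> float:
    """Dispatch MF(x,t) by parameter type."""
    if isinstance(params, SDParams):
        return mf_sd(params, profile, x, t, baseline=baseline)
    return mf_it(params, profile, x, t, baseline=baseline)


# ---------------------------------------------------------------------------
# Posterior propagation
# ---------------------------------------------------------------------------

def endpoint_distribution(posterior, endpoint_fn, grid, endpoint_kind: str = "LC",
                          max_undefined_frac: float = 0.5) -> pd.DataFrame:
    """Propagate a joint posterior through an endpoint function.

    ``endpoint_fn(params, g)`` is evaluated for every draw of ``posterior``
    (a PosteriorSample) and every value ``g`` of ``grid``.  Draws where the
    endpoint is undefined (raises or returns non-finite) are dropped with a
    logged count; more than ``max_undefined_frac`` undefined draws at any
    grid value is an error.

    Returns a DataFrame with columns grid, median, q025, q975, n_dropped.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    param_objs = posterior.param_objects()
    if not param_objs:
        raise ValueError("posterior has no draws")
    rows = []
    for g in grid:
        vals = []
        dropped = 0
        for p in param_objs:
            try:
                v = endpoint_fn(p, g)
            except (ValueError, RuntimeError, OverflowError):
                dropped += 1
                continue
            if np.isfinite(v):
                vals.append(v)
            else:
                dropped += 1
        if dropped:
            logger.info("endpoint %s at grid=%g: dropped %d/%d undefined draws",
                        endpoint_kind, g, dropped, len(param_objs))
        if dropped > max_undefined_frac * len(param_objs):
            raise RuntimeError(
                f"endpoint {endpoint_kind} undefined for {dropped}/{len(param_objs)} draws at grid={g}"
            )
        q025, med, q975 = np.quantile(vals, [0.025, 0.5, 0.975])
        rows.append({"grid": g, "median": med, "q025": q025, "q975": q975,
                     "n_dropped": dropped})
    out = pd.DataFrame(rows)
    out.attrs["endpoint_kind"] = endpoint_kind
    out.attrs["model_tag"] = posterior.model_tag
    return out
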
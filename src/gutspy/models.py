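"""Reduced GUTS toxicokinetic-toxicodynamic mathematics.

Toxicokinetics: the scaled internal damage D_w(t) follows one-compartment
first-order kinetics driven by the external concentration,

    dD_w/dt = k_d (C_w(t) - D_w(t)),   D_w(0) = 0,

with dominant rate constant k_d [1/day].  On every interval where C_w is
constant or linear this ODE has a closed form, so damage is propagated
segment by segment with no numerical integrator.

Toxicodynamics, stochastic death (SD): a common internal threshold z; the
hazard rate is h(t) = b_w * max(D_w(t) - z, 0) + h_b, with killing rate
b_w and background hazard h_b, and S(t) = exp(-int_0^t h).  The hazard
integral is evaluated analytically per segment, with threshold-crossing
times located in closed form (constant forcing) or by bracketed
root-solve (linear forcing).

Toxicodynamics, individual tolerance (IT): thresholds are log-logistic
across individuals (median m_w, shape beta); death is immediate at the
first exceedance, so

    S(t) = exp(-h_b t) * (1 - F(max_{0<tau<t} D_w(tau))),
    F(x) = 1 / (1 + (x / m_w)^(-beta)).

Calibration uses the conditional-binomial likelihood between consecutive
observation times: N(t_i) ~ Binomial(N(t_{i-1}), S(t_i)/S(t_{i-1})).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .exposure import ExposureProfile

__all__ = [
    "SDParams",
    "ITParams",
    "SurvivalTimeSeries",
    "SurvivalDataset",
    "scaled_damage",
    "max_damage",
    "depuration_time",
    "survival_sd",
    "survival_it",
    "log_likelihood",
]

logger = logging.getLogger(__name__)

_S_FLOOR = 1e-300  # survival floor before taking logs


@dataclass(frozen=True)
class SDParams:
    """GUTS-RED-SD parameters.

    k_d : dominant rate constant [1/day], > 0
    b_w : killing rate [1/(conc·day)], > 0
    z   : internal threshold [conc], >= 0
    h_b : background hazard [1/day], >= 0
    """

    k_d: float
    b_w: float
    z: float
    h_b: float

    def __post_init__(self):
        vals = (self.k_d, self.b_w, self.z, self.h_b)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SD parameters must be finite")
        if self.k_d <= 0 or self.b_w <= 0 or self.z < 0 or self.h_b < 0:
            raise ValueError("require k_d > 0, b_w > 0, z >= 0, h_b >= 0")

    names = ("k_d", "b_w", "z", "h_b")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_d, self.b_w, self.z, self.h_b])


@dataclass(frozen=True)
class ITParams:
    """GUTS-RED-IT parameters.

    k_d  : dominant rate constant [1/day], > 0
    m_w  : median of the log-logistic threshold distribution [conc], > 0
    beta : shape of the threshold distribution [-], > 0
    h_b  : background hazard [1/day], >= 0
    """

    k_d: float
    m_w: float
    beta: float
    h_b: float

    def __post_init__(self):
        vals = (self.k_d, self.m_w, self.beta, self.h_b)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("IT parameters must be finite")
        if self.k_d <= 0 or self.m_w <= 0 or self.beta <= 0 or self.h_b < 0:
            raise ValueError("require k_d > 0, m_w > 0, beta > 0, h_b >= 0")

    names = ("k_d", "m_w", "beta", "h_b")

    def as_array(self) -> np.ndarray:
        return np.array([self.k_d, self.m_w, self.beta, self.h_b])


GutsParams = Union[SDParams, ITParams]


def model_tag_of(params: GutsParams) -> str:
    return "SD" if isinstance(params, SDParams) else "IT"


@dataclass(frozen=True)
class SurvivalTimeSeries:
    """Survival counts over time for one exposure profile."""

    profile: ExposureProfile
    obs_times: np.ndarray
    n_surv: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.obs_times, dtype=float)
        n = np.asarray(self.n_surv, dtype=int)
        if t.ndim != 1 or n.ndim != 1 or t.size != n.size or t.size < 1:
            raise ValueError("obs_times and n_surv must be equal-length 1-d sequences")
        if t[0] != 0.0 or (t.size > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("obs_times must start at 0 and strictly increase")
        if np.any(np.diff(n) > 0):
            raise ValueError("survivor counts must be non-increasing over time")
        if n[0] <= 0 or np.any(n < 0):
            raise ValueError("initial count must be positive and counts non-negative")
        object.__setattr__(self, "obs_times", t)
        object.__setattr__(self, "n_surv", n)

    @property
    def n_init(self) -> int:
        return int(self.n_surv[0])

    @property
    def n_transitions(self) -> int:
        """Number of count transitions (observation intervals)."""
        return self.obs_times.size - 1


@dataclass(frozen=True)
class SurvivalDataset:
    """One or more survival time series sharing concentration units."""

    series: tuple

    def __init__(self, series: Sequence[SurvivalTimeSeries]):
        series = tuple(series)
        if not series:
            raise ValueError("dataset needs at least one series")
        labels = [s.profile.label for s in series]
        if len(set(labels)) != len(labels):
            raise ValueError("profile labels must be unique within a dataset")
        object.__setattr__(self, "series", series)

    @property
    def n_obs(self) -> int:
        """Total number of count transitions across series."""
        return sum(s.n_transitions for s in self.series)

    @property
    def is_constant(self) -> bool:
        return all(s.profile.is_constant for s in self.series)

    def concentrations_tested(self) -> np.ndarray:
        return np.unique(np.concatenate([s.profile.concentrations for s in self.series]))


# ---------------------------------------------------------------------------
# Toxicokinetics: piecewise-analytic damage
# ---------------------------------------------------------------------------

def _segment_table(profile: ExposureProfile):
    """Forcing segments (start, c0, slope); the last extends to +inf."""
    t, c = profile.times, profile.concentrations
    if t.size == 1:
        return np.array([0.0]), np.array([c[0]]), np.array([0.0])
    starts = t.copy()
    if profile.interpolation == "linear":
        slopes = np.append(np.diff(c) / np.diff(t), 0.0)
        c0 = c.copy()
    else:
        slopes = np.zeros_like(c)
        c0 = c.copy()
    return starts, c0, slopes


def _damage_at(u, D0, c0, s, k_d):
    """Damage within one segment: closed form of the linear-forcing ODE.

    D(u) = c0 + s*u - s/k_d + (D0 - c0 + s/k_d) * exp(-k_d*u)
    """
    A = D0 - c0 + s / k_d
    return c0 + s * u - s / k_d + A * np.exp(-k_d * u)


def scaled_damage(profile: ExposureProfile, k_d: float, t_grid) -> np.ndarray:
    """Scaled internal damage D_w(t) on ``t_grid``, exactly per segment.

    D_w(0) = 0; for constant exposure this reduces to
    D_w(t) = C_w (1 - exp(-k_d t)).
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    starts, c0s, slopes = _segment_table(profile)
    out = np.empty_like(t_grid)
    # damage at every segment start
    D_start = np.empty(starts.size)
    D_start[0] = 0.0
    for k in range(starts.size - 1):
        D_start[k + 1] = _damage_at(starts[k + 1] - starts[k], D_start[k], c0s[k], slopes[k], k_d)
    seg = np.clip(np.searchsorted(starts, t_grid, side="right") - 1, 0, starts.size - 1)
    for k in np.unique(seg):
        m = seg == k
        out[m] = _damage_at(t_grid[m] - starts[k], D_start[k], c0s[k], slopes[k], k_d)
    return out


def _segment_running_max(D0, c0, s, k_d, U):
    """Max of damage over [0, U] within one segment (U may be inf for s=0)."""
    A = D0 - c0 + s / k_d
    cands = [D0]
    if np.isfinite(U):
        cands.append(_damage_at(U, D0, c0, s, k_d))
    else:
        cands.append(c0)  # s == 0: D -> c0 as u -> inf
    if s != 0.0 and A != 0.0:
        r = s / (k_d * A)
        if r > 0:
            u_m = -math.log(r) / k_d
            if 0.0 < u_m < U:
                cands.append(_damage_at(u_m, D0, c0, s, k_d))
    return max(cands)


def max_damage(profile: ExposureProfile, k_d: float, t: float) -> float:
    """Running maximum of scaled damage over [0, t].

    For constant exposure this equals C_w (1 - exp(-k_d t)); after an
    isolated pulse the maximum is attained at the pulse end.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    return float(running_max_damage(profile, k_d, [t])[0])


def running_max_damage(profile: ExposureProfile, k_d: float, t_grid) -> np.ndarray:
    """max_{0<tau<=t} D_w(tau) evaluated on ``t_grid``."""
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    starts, c0s, slopes = _segment_table(profile)
    n_seg = starts.size
    D_start = np.empty(n_seg)
    D_start[0] = 0.0
    for k in range(n_seg - 1):
        D_start[k + 1] = _damage_at(starts[k + 1] - starts[k], D_start[k], c0s[k], slopes[k], k_d)
    # running max at each segment start
    M_start = np.empty(n_seg)
    M_start[0] = 0.0
    for k in range(n_seg - 1):
        U = starts[k + 1] - starts[k]
        M_start[k + 1] = max(M_start[k], _segment_running_max(D_start[k], c0s[k], slopes[k], k_d, U))
    out = np.empty_like(t_grid)
    seg = np.clip(np.searchsorted(starts, t_grid, side="right") - 1, 0, n_seg - 1)
    for i, (t, k) in enumerate(zip(t_grid, seg)):
        u = t - starts[k]
        if u == 0.0:
            out[i] = M_start[k]
        else:
            out[i] = max(M_start[k], _segment_running_max(D_start[k], c0s[k], slopes[k], k_d, u))
    return out


def depuration_time(k_d: float, x: float) -> float:
    """Time after a pulse for the scaled damage to fall by x percent.

    DRT_x = -ln(1 - x/100) / k_d; DRT_50 is the damage half-life ln(2)/k_d.
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    if not (0 < x < 100):
        raise ValueError("x must be in (0, 100)")
    return -math.log1p(-x / 100.0) / k_d


# ---------------------------------------------------------------------------
# SD hazard integral
# ---------------------------------------------------------------------------

def _exceed_antideriv(u, A, B, s, k_d):
    """Antiderivative of f(u) = A e^{-k_d u} + B + s u."""
    return -A / k_d * np.exp(-k_d * u) + B * u + 0.5 * s * u * u


def _segment_crossings(A, B, s, k_d, U):
    """Zeros of f(u) = A e^{-k_d u} + B + s u on (0, U).

    f has at most one interior extremum, hence at most two zeros.  Constant
    forcing (s = 0) admits a closed form; otherwise brentq on the monotone
    pieces (bracketed, xtol 1e-14).
    """
    pieces = [0.0]
    if s != 0.0 and A != 0.0:
        r = s / (k_d * A)
        if r > 0:
            u_m = -math.log(r) / k_d
            if 0.0 < u_m < U:
                pieces.append(u_m)
    pieces.append(U)

    def f(u):
        return A * math.exp(-k_d * u) + B + s * u

    zeros = []
    for a, b in zip(pieces[:-1], pieces[1:]):
        fa, fb = f(a), f(b)
        if fa == 0.0 and a > 0.0:
            zeros.append(a)
            continue
        if fa * fb < 0:
            if s == 0.0:
                # A e^{-k u} = -B  =>  u = -ln(-B/A)/k
                zeros.append(-math.log(-B / A) / k_d)
            else:
                zeros.append(brentq(f, a, b, xtol=1e-14, rtol=8.9e-16))
    return sorted(set(zeros))


def exceedance_integral(profile: ExposureProfile, k_d: float, z: float, t_grid) -> np.ndarray:
    """Cumulative threshold exceedance H(t) = int_0^t max(D_w(tau) - z, 0) dtau.

    Evaluated analytically on the same segmentation as ``scaled_damage``,
    with crossing times from :func:`_segment_crossings`.
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    t_max = float(t_grid.max(initial=0.0))

    starts, c0s, slopes = _segment_table(profile)
    n_seg = starts.size
    D_start = np.empty(n_seg)
    D_start[0] = 0.0
    for k in range(n_seg - 1):
        D_start[k + 1] = _damage_at(starts[k + 1] - starts[k], D_start[k], c0s[k], slopes[k], k_d)

    def seg_integral(k, u):
        """int_0^u max(f, 0) within segment k (u <= segment length)."""
        if u <= 0.0:
            return 0.0
        A = D_start[k] - c0s[k] + slopes[k] / k_d
        B = c0s[k] - slopes[k] / k_d - z
        cuts = [c for c in _segment_crossings(A, B, slopes[k], k_d, u)] + [u]
        total, lo = 0.0, 0.0
        for hi in cuts:
            if hi <= lo:
                continue
            mid = 0.5 * (lo + hi)
            if A * math.exp(-k_d * mid) + B + slopes[k] * mid > 0:
                total += _exceed_antideriv(hi, A, B, slopes[k], k_d) - _exceed_antideriv(
                    lo, A, B, slopes[k], k_d
                )
            lo = hi
        return total

    # cumulative integral at segment starts (only up to t_max)
    H_start = np.zeros(n_seg)
    for k in range(n_seg - 1):
        if starts[k] >= t_max:
            H_start[k + 1] = H_start[k]
            continue
        U = min(starts[k + 1], t_max) - starts[k]
        H_start[k + 1] = H_start[k] + seg_integral(k, U)

    out = np.empty_like(t_grid)
    seg = np.clip(np.searchsorted(starts, t_grid, side="right") - 1, 0, n_seg - 1)
    for i, (t, k) in enumerate(zip(t_grid, seg)):
        out[i] = H_start[k] + seg_integral(k, t - starts[k])
    return out


# ---------------------------------------------------------------------------
# Survival probabilities
# ---------------------------------------------------------------------------

def survival_sd(params: SDParams, profile: ExposureProfile, t_grid) -> np.ndarray:
    """GUTS-RED-SD survival probability S(t) on ``t_grid``.

    S(t) = exp(-h_b t - b_w H(t)) with H the cumulative threshold
    exceedance of the scaled damage.  S(0) = 1 and S is non-increasing.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    H = exceedance_integral(profile, params.k_d, params.z, t_grid)
    S = np.exp(-params.h_b * t_grid - params.b_w * H)
    return np.maximum(S, _S_FLOOR)


def loglogistic_cdf(x, m_w: float, beta: float):
    """Log-logistic CDF F(x) = 1 / (1 + (x/m_w)^(-beta)), F(0) = 0.

    Evaluated as expit(beta * ln(x/m_w)) to avoid overflow at extreme
    shape values.
    """
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = expit(beta * np.log(x[pos] / m_w))
    return out


def survival_it(params: ITParams, profile: ExposureProfile, t_grid) -> np.ndarray:
    """GUTS-RED-IT survival probability S(t) on ``t_grid``.

    S(t) = exp(-h_b t) (1 - F(max damage up to t)); non-increasing because
    the running damage maximum is non-decreasing.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    M = running_max_damage(profile, params.k_d, t_grid)
    S = np.exp(-params.h_b * t_grid) * (1.0 - loglogistic_cdf(M, params.m_w, params.beta))
    return np.maximum(S, _S_FLOOR)


def survival(params: GutsParams, profile: ExposureProfile, t_grid) -> np.ndarray:
    """Dispatch to :func:`survival_sd` or :func:`survival_it` by params type."""
    if isinstance(params, SDParams):
        return survival_sd(params, profile, t_grid)
    return survival_it(params, profile, t_grid)


# ---------------------------------------------------------------------------
# Conditional-binomial likelihood
# ---------------------------------------------------------------------------

def _binom_logpmf(k, n, p):
    """log Binomial(n, p) mass at k, safe at p in {0, 1}."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.full(np.broadcast(k, n, p).shape, -np.inf)
    comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        core = comb + k * np.log(p) + (n - k) * np.log1p(-p)
    ok = (p > 0) & (p < 1)
    out = np.where(ok, np.where(np.isfinite(core), core, -np.inf), out)
    out = np.where((p == 0) & (k == 0), 0.0, out)
    out = np.where((p == 1) & (k == n), 0.0, out)
    return out


def conditional_probabilities(params: GutsParams, series: SurvivalTimeSeries) -> np.ndarray:
    """S(t_i)/S(t_{i-1}) on the series' observation grid, clamped to [0, 1]."""
    S = survival(params, series.profile, series.obs_times)
    p = S[1:] / S[:-1]
    if np.any(p > 1.0 + 1e-12):
        logger.warning("survival ratio > 1 clamped to 1 (numerical)")
    return np.clip(p, 0.0, 1.0)


def log_likelihood(params: GutsParams, dataset: SurvivalDataset, model_tag: str | None = None) -> float:
    """Conditional-binomial log-likelihood of a dataset.

    Sums over all series and consecutive observation intervals the mass of
    N(t_i) ~ Binomial(N(t_{i-1}), S(t_i)/S(t_{i-1})).  Returns -inf when
    the data are impossible under ``params`` (e.g. observed deaths while
    the conditional survival probability is exactly 1).
    """
    if model_tag is not None and model_tag != model_tag_of(params):
        raise ValueError(f"params are {model_tag_of(params)} but model_tag={model_tag}")
    total = 0.0
    for s in dataset.series:
        if s.n_transitions == 0:
            continue
        p = conditional_probabilities(params, s)
        ll = _binom_logpmf(s.n_surv[1:], s.n_surv[:-1], p)
        total += float(np.sum(ll))
    return total


# ---------------------------------------------------------------------------
# Vectorised constant-exposure survival (used by the sampler on constant
# designs; must agree with survival_sd / survival_it exactly)
# ---------------------------------------------------------------------------

def sd_survival_constant(k_d, b_w, z, h_b, C, t):
    """Vectorised S_SD under constant exposure; inputs broadcast.

    Uses the closed-form hazard integral with
    t_z = -ln(1 - z/C)/k_d for C > z, else no exceedance.
    """
    k_d, b_w, z, h_b, C, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (k_d, b_w, z, h_b, C, t))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_z = np.where(C > z, -np.log1p(-np.minimum(z / np.where(C > 0, C, 1.0), 1.0)) / k_d, np.inf)
        dt = t - t_z
        H = np.where(
            (C > z) & (dt > 0),
            (C - z) * dt + C * (np.exp(-k_d * t) - np.exp(-k_d * t_z)) / k_d,
            0.0,
        )
    S = np.exp(-h_b * t - b_w * H)
    return np.maximum(S, _S_FLOOR)


def it_survival_constant(k_d, m_w, beta, h_b, C, t):
    """Vectorised S_IT under constant exposure; inputs broadcast."""
    k_d, m_w, beta, h_b, C, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (k_d, m_w, beta, h_b, C, t))
    )
    from scipy.special import expit

    M = C * -np.expm1(-k_d * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(M > 0, expit(beta * np.log(np.where(M > 0, M, 1.0) / m_w)), 0.0)
    S = np.exp(-h_b * t) * (1.0 - F)
    return np.maximum(S, _S_FLOOR)
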
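"""Exposure-concentration profiles C_w(t).

A profile is a time-stamped series of external concentrations together with
an interpolation rule.  Two rules are supported:

* ``"linear"`` — piecewise-linear between knots; the natural choice for
  measured water-chemistry series.
* ``"step"`` — piecewise-constant, holding the value of the knot at or
  before ``t`` (left knot); exact for designed rectangular pulses.

Beyond the last knot the profile holds its last value, so predictions may
extend past the exposure record.  Time is in days with ``t = 0`` the start
of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ExposureProfile", "make_pulse_profile", "constant_profile", "auc"]

_INTERP_RULES = ("linear", "step")


@dataclass(frozen=True)
class ExposureProfile:
    """External concentration forcing C_w(t).

    Parameters
    ----------
    label : str
        Identifier, unique within a dataset.
    times : array-like
        Strictly increasing time points [days], first equal to 0.
    concentrations : array-like
        Non-negative concentrations, one per time point.  A single
        (time, conc) pair denotes constant exposure for all t >= 0.
    interpolation : {"linear", "step"}
        Rule between knots; see module docstring.
    """

    label: str
    times: np.ndarray
    concentrations: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size or t.size < 1:
            raise ValueError("times and concentrations must be equal-length 1-d sequences")
        if t[0] != 0.0:
            raise ValueError("first time point must be 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and non-negative")
        if self.interpolation not in _INTERP_RULES:
            raise ValueError(f"interpolation must be one of {_INTERP_RULES}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def is_constant(self) -> bool:
        """True when C_w(t) is the same for all t."""
        return self.times.size == 1 or np.all(self.concentrations == self.concentrations[0])

    def concentration_at(self, t) -> np.ndarray | float:
        """Evaluate C_w(t) under the profile's interpolation rule.

        Beyond the last knot the last concentration is held.  Negative
        times are a domain error.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be non-negative")
        knots, conc = self.times, self.concentrations
        if knots.size == 1:
            out = np.full_like(t_arr, conc[0], dtype=float)
        elif self.interpolation == "linear":
            out = np.interp(t_arr, knots, conc)
        else:  # step: value of the knot at or before t
            idx = np.searchsorted(knots, t_arr, side="right") - 1
            out = conc[np.clip(idx, 0, conc.size - 1)]
        return out if t_arr.ndim else float(out)

    def scaled(self, factor: float) -> "ExposureProfile":
        """Profile with every concentration multiplied by ``factor`` >= 0."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return ExposureProfile(
            self.label, self.times.copy(), self.concentrations * factor, self.interpolation
        )

    def auc(self, t0: float, t1: float) -> float:
        """Exact integral of C_w over [t0, t1]."""
        return auc(self, t0, t1)


def constant_profile(conc: float, label: str = "constant") -> ExposureProfile:
    """Constant exposure at concentration ``conc`` for all t >= 0."""
    return ExposureProfile(label, np.array([0.0]), np.array([float(conc)]), "step")


def make_pulse_profile(
    n_pulses: int,
    amplitude: float,
    width: float,
    start_times: Sequence[float],
    total_duration: float,
    label: str = "pulses",
) -> ExposureProfile:
    """Rectangular-pulse profile: ``n_pulses`` pulses of given amplitude and
    width at ``start_times``, zero in between, over ``total_duration`` days.

    Pulses must be non-overlapping and fit within the total duration.
    """
    starts = np.sort(np.asarray(start_times, dtype=float))
    if starts.size != n_pulses:
        raise ValueError(f"expected {n_pulses} start times, got {starts.size}")
    if amplitude < 0 or width <= 0:
        raise ValueError("amplitude must be >= 0 and width > 0")
    if starts.size and (starts[0] < 0 or starts[-1] + width > total_duration):
        raise ValueError("pulses must fit within [0, total_duration]")
    if np.any(np.diff(starts) < width):
        raise ValueError("pulses overlap")

    times: list[float] = [0.0]
    concs: list[float] = [0.0]
    for s in starts:
        if s == 0.0:
            concs[0] = amplitude
        else:
            times.append(s)
            concs.append(amplitude)
        times.append(s + width)
        concs.append(0.0)
    if times[-1] < total_duration:
        times.append(total_duration)
        concs.append(0.0)
    return ExposureProfile(label, np.array(times), np.array(concs), "step")


def auc(profile: ExposureProfile, t0: float, t1: float) -> float:
    """Exact area under the interpolated profile over [t0, t1].

    Additive over adjacent intervals; the last concentration is held
    beyond the exposure record.
    """
    if t0 < 0 or t1 <= t0:
        raise ValueError("need 0 <= t0 < t1")
    knots = profile.times
    # integration breakpoints: interval ends plus interior knots
    pts = np.concatenate([[t0], knots[(knots > t0) & (knots < t1)], [t1]])
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if profile.interpolation == "linear" and knots.size > 1:
            ca = profile.concentration_at(a)
            cb = profile.concentration_at(b)
            total += 0.5 * (ca + cb) * (b - a)
        else:
            total += profile.concentration_at(a) * (b - a)
    return total
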
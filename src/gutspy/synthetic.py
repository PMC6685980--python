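"""Synthetic survival experiments with known ground-truth parameters.

Emulates the two kinds of Gammarus pulex toxicity-test designs used for
calibration:

* constant designs — 8 constant-concentration profiles (a control plus a
  7-step geometric ladder), 5 observation times over 4 days, 20
  individuals per profile (40 records);
* variable designs — 2-4 double-pulse profiles (two one-day pulses with a
  short or long interval) over 10-22 days with uneven observation grids
  and 70-80 individuals per profile.

Counts are drawn by the conditional-binomial forward model
N(t_i) ~ Binomial(N(t_{i-1}), S(t_i)/S(t_{i-1})), deterministic given a
single integer seed (per-profile streams are spawned from it).

Because the tested concentrations of the original experiments are not
published, the constant ladder spans [thr/4, 4*thr] of the generating
threshold (z or m_w), which guarantees profiles both below and above the
threshold — informative data for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exposure import ExposureProfile, constant_profile, make_pulse_profile
from .models import (
    GutsParams,
    SurvivalDataset,
    SurvivalTimeSeries,
    model_tag_of,
    survival,
)

__all__ = [
    "ExperimentalDesign",
    "simulate_dataset",
    "table1_design",
    "figure_experiment_profiles",
    "TABLE1_ROWS",
]

# Per-compound design characteristics: constant rows are identical
# (40 records = 8 profiles x 5 times, N_init 20, 4 days); variable rows
# differ in series count, N_init, duration and per-profile observation
# counts (their sum is the record count).
TABLE1_ROWS = {
    "carbendazim": {"n_series": 4, "n_init": 80, "days": 10, "points": (8, 14, 16, 13)},
    "cypermethrin": {"n_series": 4, "n_init": 80, "days": 10, "points": (10, 18, 18, 15)},
    "dimethoate": {"n_series": 4, "n_init": 80, "days": 10, "points": (10, 16, 17, 15)},
    "malathion": {"n_series": 2, "n_init": 70, "days": 22, "points": (35, 35)},
    "propiconazole": {"n_series": 4, "n_init": 70, "days": 10, "points": (11, 21, 21, 21)},
}

_CONSTANT_ROW = {"n_profiles": 8, "n_times": 5, "n_init": 20, "days": 4}


@dataclass(frozen=True)
class ExperimentalDesign:
    """Exposure profiles with their observation grids and cohort sizes."""

    profiles: tuple
    obs_times: tuple  # one increasing array per profile, first = 0
    n_init: tuple

    def __post_init__(self):
        if not (len(self.profiles) == len(self.obs_times) == len(self.n_init)):
            raise ValueError("profiles, obs_times and n_init must align")
        for t, n in zip(self.obs_times, self.n_init):
            t = np.asarray(t, dtype=float)
            if t[0] != 0 or np.any(np.diff(t) <= 0):
                raise ValueError("observation grids must start at 0 and increase")
            if n <= 0:
                raise ValueError("n_init must be positive")

    @property
    def n_records(self) -> int:
        return sum(len(t) for t in self.obs_times)


def simulate_dataset(
    params: GutsParams,
    design: ExperimentalDesign,
    seed: int,
    model_tag: str | None = None,
) -> SurvivalDataset:
    """Forward-simulate survivor counts under known GUTS parameters.

    Per profile, N(0) = n_init and N(t_i) ~ Binomial(N(t_{i-1}),
    S(t_i)/S(t_{i-1})); identical seeds give identical datasets.
    """
    if model_tag is not None and model_tag != model_tag_of(params):
        raise ValueError("model_tag does not match the parameter type")
    streams = np.random.SeedSequence(seed).spawn(len(design.profiles))
    series = []
    for prof, t_obs, n0, ss in zip(design.profiles, design.obs_times, design.n_init, streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        t_obs = np.asarray(t_obs, dtype=float)
        S = survival(params, prof, t_obs)
        p = np.clip(S[1:] / S[:-1], 0.0, 1.0)
        counts = np.empty(t_obs.size, dtype=int)
        counts[0] = n0
        for i, pi in enumerate(p):
            counts[i + 1] = rng.binomial(counts[i], pi)
        series.append(SurvivalTimeSeries(prof, t_obs, counts))
    return SurvivalDataset(series)


def _uneven_grid(duration: float, m: int, pulse_times: Sequence[float]) -> np.ndarray:
    """Deterministic uneven observation grid of m points on [0, duration].

    Starts from mandatory points (0, the end, pulse starts/ends and the
    day after each pulse end), then greedily adds quarter-day candidates
    farthest from the current set — observations cluster around pulses.
    """
    pts = {0.0, float(duration)}
    for s in pulse_times:
        for c in (s, s + 1.0, s + 2.0):
            if 0 < c < duration:
                pts.add(float(c))
    pts = sorted(pts)[:m]
    cand = np.round(np.arange(0, duration + 1e-9, 0.25), 6)
    while len(pts) < m:
        arr = np.asarray(pts)
        dists = np.min(np.abs(cand[:, None] - arr[None, :]), axis=1)
        best = int(np.argmax(dists))
        if dists[best] <= 0:
            break
        pts.append(float(cand[best]))
        pts.sort()
    return np.asarray(sorted(pts))


def table1_design(kind: str, compound: str, threshold: float = 1.0,
                  amplitude: float | None = None) -> ExperimentalDesign:
    """Experimental design matching the published per-compound layout.

    kind="constant": 8 constant profiles (control + geometric ladder over
    [threshold/4, 4*threshold]), observation times 0..4 days, 20
    individuals each.  kind="variable": the compound's number of
    double-pulse profiles, duration, N_init and per-profile observation
    counts; pulses are one day wide with a 2-day (short) or 7-day (long)
    interval, at ``amplitude`` (default 4*threshold).
    """
    if compound not in TABLE1_ROWS:
        raise ValueError(f"unknown compound {compound!r}; know {sorted(TABLE1_ROWS)}")
    if kind == "constant":
        row = _CONSTANT_ROW
        ladder = np.geomspace(threshold / 4.0, 4.0 * threshold, row["n_profiles"] - 1)
        concs = np.concatenate([[0.0], ladder])
        profiles = tuple(
            constant_profile(c, label=f"{compound}-cst-{i}") for i, c in enumerate(concs)
        )
        t_obs = np.linspace(0.0, row["days"], row["n_times"])
        return ExperimentalDesign(
            profiles, tuple(t_obs.copy() for _ in profiles),
            tuple(row["n_init"] for _ in profiles),
        )
    if kind != "variable":
        raise ValueError("kind must be 'constant' or 'variable'")
    row = TABLE1_ROWS[compound]
    amp = 4.0 * threshold if amplitude is None else amplitude
    gaps = [2.0, 7.0]  # days between pulse end and next pulse start
    amps = [amp, amp / 2.0]
    profiles, grids = [], []
    for i in range(row["n_series"]):
        gap = gaps[i % 2]
        a = amps[i // 2] if row["n_series"] > 2 else amp
        starts = [1.0, 2.0 + gap]
        profiles.append(
            make_pulse_profile(2, a, 1.0, starts, row["days"],
                               label=f"{compound}-var-{i}")
        )
        grids.append(_uneven_grid(row["days"], row["points"][i], starts))
    return ExperimentalDesign(
        tuple(profiles), tuple(grids), tuple(row["n_init"] for _ in profiles)
    )


def figure_experiment_profiles(which: str, amplitude: float = 1.0) -> list:
    """Equal-dose pulse families used in the design-exploration simulations.

    which="pulse_number": three 20-day profiles with 9, 6 and 3 one-day
    pulses and amplitudes a, 1.5a, 3a — identical area under the curve.
    which="pulse_interval": three two-pulse profiles (one-day pulses,
    same amplitude) with 0.5, 2 and 7 days between the pulses.
    """
    if which == "pulse_number":
        out = []
        for n, step in ((9, 2.0), (6, 3.0), (3, 6.0)):
            amp = amplitude * 9.0 / n
            starts = [i * step for i in range(n)]
            out.append(make_pulse_profile(n, amp, 1.0, starts, 20.0,
                                          label=f"{n}-pulses"))
        return out
    if which == "pulse_interval":
        out = []
        for gap in (0.5, 2.0, 7.0):
            starts = [1.0, 2.0 + gap]
            out.append(make_pulse_profile(2, amplitude, 1.0, starts, 14.0,
                                          label=f"gap-{gap}"))
        return out
    raise ValueError("which must be 'pulse_number' or 'pulse_interval'")
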
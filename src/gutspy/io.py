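"""File formats and the pipeline runner.

Survival CSV: columns ``profile,time,conc,Nsurv`` (the ``conc`` column is
optional when a separate exposure CSV is supplied).  Exposure CSV:
columns ``profile,time,conc``; one file may hold several profiles.  All
outputs are plain CSV/JSON; a manifest records versions, seed and a
configuration hash so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import ExposureProfile
from .models import SurvivalDataset, SurvivalTimeSeries

__all__ = [
    "read_exposure_csv",
    "read_survival_csv",
    "write_survival_csv",
    "write_exposure_csv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_exposure_csv(path, interpolation: str = "linear") -> dict:
    """Read exposure profiles; returns {label: ExposureProfile}."""
    df = pd.read_csv(path)
    required = {"profile", "time", "conc"}
    if not required.issubset(df.columns):
        raise ValueError(f"exposure CSV needs columns {sorted(required)}, got {list(df.columns)}")
    profiles = {}
    for label, g in df.groupby("profile", sort=False):
        g = g.sort_values("time")
        profiles[str(label)] = ExposureProfile(
            str(label), g["time"].to_numpy(float), g["conc"].to_numpy(float), interpolation
        )
    return profiles


def read_survival_csv(path, exposure_csv=None, interpolation: str = "linear") -> SurvivalDataset:
    """Read a survival dataset, validating counts row by row.

    Non-monotone survivor counts, negative values and malformed rows are
    rejected with messages naming the offending CSV rows (1-based, header
    excluded).
    """
    df = pd.read_csv(path)
    need = {"profile", "time", "Nsurv"}
    if not need.issubset(df.columns):
        raise ValueError(f"survival CSV needs columns {sorted(need)}, got {list(df.columns)}")
    has_conc = "conc" in df.columns
    if not has_conc and exposure_csv is None:
        raise ValueError("survival CSV has no 'conc' column and no exposure CSV was supplied")
    df = df.reset_index().rename(columns={"index": "_row"})
    df["_row"] += 1

    bad = df[(df["Nsurv"] < 0) | (df["time"] < 0)]
    if not bad.empty:
        raise ValueError(f"negative time or Nsurv at rows {bad['_row'].tolist()}")

    exposures = read_exposure_csv(exposure_csv, interpolation) if exposure_csv else None
    series = []
    for label, g in df.groupby("profile", sort=False):
        g = g.sort_values("time")
        inc = g["Nsurv"].to_numpy()
        rising = np.where(np.diff(inc) > 0)[0]
        if rising.size:
            rows = g["_row"].to_numpy()[rising + 1].tolist()
            raise ValueError(f"survivor counts increase in profile {label!r} at rows {rows}")
        if exposures is not None:
            if str(label) not in exposures:
                raise ValueError(f"profile {label!r} missing from the exposure CSV")
            prof = exposures[str(label)]
        else:
            prof = ExposureProfile(
                str(label), g["time"].to_numpy(float), g["conc"].to_numpy(float), interpolation
            )
        series.append(
            SurvivalTimeSeries(prof, g["time"].to_numpy(float), g["Nsurv"].to_numpy(int))
        )
    return SurvivalDataset(series)


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    rows = []
    for s in dataset.series:
        conc = s.profile.concentration_at(s.obs_times)
        for t, c, n in zip(s.obs_times, np.atleast_1d(conc), s.n_surv):
            rows.append({"profile": s.profile.label, "time": t, "conc": c, "Nsurv": n})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_exposure_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"profile": p.label, "time": t, "conc": c})
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat configuration of one calibration run.

    ``model`` may be "SD", "IT" or "both" (fit both and emit a
    side-by-side endpoint table, from which the more conservative value
    can be read off).
    """

    data: str
    out: str
    model: str = "SD"
    exposure: str | None = None
    seed: int = 0
    chains: int = 3
    warmup: int = 5000
    draws: int = 5000
    walkers: int = 16
    x_grid: tuple = (10.0, 20.0, 50.0)
    t_grid: tuple = ()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value text file (lists comma-separated)."""
        kv = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected key=value, got {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        conv = {
            "seed": int, "chains": int, "warmup": int, "draws": int, "walkers": int,
            "x_grid": lambda s: tuple(float(x) for x in s.split(",")),
            "t_grid": lambda s: tuple(float(x) for x in s.split(",")),
        }
        for k, f in conv.items():
            if k in kv:
                kv[k] = f(kv[k])
        return cls(**kv)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fit_one(dataset, tag, cfg) -> dict:
    from .inference import GUTSModel

    res = GUTSModel(dataset, model=tag).fit(
        seed=cfg.seed, chains=cfg.chains, warmup=cfg.warmup,
        draws=cfg.draws, walkers=cfg.walkers,
    )
    return res


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> endpoints workflow over one dataset.

    Fits the requested model(s), writes the posterior draws, diagnostics,
    goodness-of-fit report, survival credible bands per profile, and
    LC / MF endpoint tables; a manifest ties outputs to the seed and the
    configuration hash.  Returns {model_tag: GUTSResults}.
    """
    import gutspy

    data_path = Path(config.data)
    if not data_path.exists():
        raise FileNotFoundError(f"survival data file not found: {data_path}")
    if config.exposure is not None and not Path(config.exposure).exists():
        raise FileNotFoundError(f"exposure file not found: {config.exposure}")
    dataset = read_survival_csv(data_path, config.exposure)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    tags = ["SD", "IT"] if config.model == "both" else [config.model]
    results, endpoint_rows, manifest_logs = {}, [], []
    for tag in tags:
        res = _fit_one(dataset, tag, config)
        results[tag] = res
        res.posterior.to_dataframe().to_csv(out / f"posterior_{tag}.csv", index=False)
        (out / f"diagnostics_{tag}.json").write_text(
            json.dumps(res.posterior.diagnostics, indent=2)
        )
        manifest_logs.extend(res.posterior.diagnostics["warnings"])
        (out / f"gof_{tag}.json").write_text(json.dumps(res.gof().to_dict(), indent=2))

        bands = []
        for s in dataset.series:
            grid = np.linspace(0, s.obs_times[-1], 41)
            band = res.predict_survival(s.profile, grid).to_frame()
            band.insert(0, "profile", s.profile.label)
            bands.append(band)
        pd.concat(bands).to_csv(out / f"survival_bands_{tag}.csv", index=False)

        t_end = max(s.obs_times[-1] for s in dataset.series)
        t_vals = config.t_grid or (t_end,)
        for x in config.x_grid:
            for t in t_vals:
                if dataset.is_constant:
                    est = res.lcx(x, t)
                    endpoint_rows.append(
                        {"endpoint": "LC", "x": x, "t": t, "median": est.median,
                         "q2.5": est.q025, "q97.5": est.q975, "model": tag}
                    )
                for s in dataset.series:
                    if s.profile.is_constant and s.profile.concentrations[0] == 0:
                        continue
                    est = res.mfx(s.profile, x, t)
                    endpoint_rows.append(
                        {"endpoint": "MF", "x": x, "t": t, "profile": s.profile.label,
                         "median": est.median, "q2.5": est.q025, "q97.5": est.q975,
                         "model": tag}
                    )
    pd.DataFrame(endpoint_rows).to_csv(out / "endpoints.csv", index=False)
    manifest = {
        "package": "gutspy",
        "version": gutspy.__version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()},
        "models": tags,
        "warnings": manifest_logs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
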
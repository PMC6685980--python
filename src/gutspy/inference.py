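"""Bayesian calibration of reduced GUTS models.

Parameters are sampled on the log10 scale with log10-uniform priors whose
default bounds are set from the experimental design: k_d so that between
0.1% and 99.9% of damage equilibrium is reachable within the experiment
duration and the shortest observation gap respectively, the threshold
(z or m_w) spanning the positive tested concentrations, and h_b capped by
worst-case control mortality.

Sampling uses affine-invariant ensembles (emcee), one independently
seeded ensemble per chain; a single user seed derives per-chain seeds
deterministically, so identical seed and settings give identical draws.
Convergence diagnostics (split R-hat, effective sample size) are computed
per parameter and attached to the posterior; R-hat > 1.05 or ESS < 100
raises a recorded warning, never a silent pass.

The module also provides the statsmodels-style front door:
``GUTSModel(dataset, model="SD").fit(seed=1)`` returns a
:class:`GUTSResults` carrying the posterior, a ``summary()`` table, and
prediction / endpoint / goodness-of-fit methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import emcee
import numpy as np
import pandas as pd

from . import endpoints as _endpoints
from .exposure import ExposureProfile
from .models import (
    GutsParams,
    ITParams,
    SDParams,
    SurvivalDataset,
    _binom_logpmf,
    it_survival_constant,
    log_likelihood,
    sd_survival_constant,
    survival,
)

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorSample",
    "CredibleBand",
    "default_priors",
    "fit",
    "predict_survival",
    "GUTSModel",
    "GUTSResults",
]

_PARAM_NAMES = {"SD": ("k_d", "b_w", "z", "h_b"), "IT": ("k_d", "m_w", "beta", "h_b")}


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter log10-uniform prior bounds (natural scale)."""

    model_tag: str
    bounds: dict  # name -> (low, high), 0 < low < high

    def __post_init__(self):
        names = _PARAM_NAMES[self.model_tag]
        if tuple(self.bounds) != names:
            raise ValueError(f"bounds must be given for {names} in order")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < math.inf):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def log10_bounds(self) -> np.ndarray:
        return np.log10(np.array(list(self.bounds.values())))

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log-prior of log10-parameters; -inf outside the box."""
        theta = np.atleast_2d(theta)
        lb = self.log10_bounds
        inside = np.all((theta >= lb[:, 0]) & (theta <= lb[:, 1]), axis=1)
        return np.where(inside, 0.0, -np.inf)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n draws of log10-parameters uniform in the prior box."""
        lb = self.log10_bounds
        return rng.uniform(lb[:, 0], lb[:, 1], size=(n, lb.shape[0]))


def default_priors(dataset: SurvivalDataset, model_tag: str) -> PriorSpec:
    """Design-informed default priors.

    k_d bounds make 0.1% of equilibrium reachable within the experiment
    duration (lower) and 99.9% within the shortest observation gap
    (upper); the threshold spans the positive tested concentrations; b_w
    and beta are log10-uniform over [1e-4, 1e4] and [1e-2, 1e2]; h_b is
    log10-uniform up to the rate at which only 5% of controls would
    survive the experiment.
    """
    if model_tag not in _PARAM_NAMES:
        raise ValueError("model_tag must be 'SD' or 'IT'")
    duration = max(s.obs_times[-1] for s in dataset.series)
    gaps = np.concatenate([np.diff(s.obs_times) for s in dataset.series])
    gaps = gaps[gaps > 0]
    if duration <= 0 or gaps.size == 0:
        raise ValueError("dataset has no observation intervals")
    shortest_gap = float(gaps.min())
    concs = dataset.concentrations_tested()
    concs = concs[concs > 0]
    if concs.size == 0:
        raise ValueError("dataset tests no positive concentration; threshold prior undefined")

    kd_lo = -math.log1p(-0.001) / duration
    kd_hi = -math.log(1 - 0.999) / shortest_gap
    thr = (float(concs.min()), float(concs.max()))
    if thr[0] == thr[1]:
        thr = (thr[0] / 10.0, thr[1] * 10.0)
    hb_hi = -math.log(0.05) / duration
    bounds = {"k_d": (kd_lo, kd_hi)}
    if model_tag == "SD":
        bounds["b_w"] = (1e-4, 1e4)
        bounds["z"] = thr
    else:
        bounds["m_w"] = thr
        bounds["beta"] = (1e-2, 1e2)
    bounds["h_b"] = (1e-5, hb_hi)
    return PriorSpec(model_tag, bounds)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings: ``chains`` independent ensembles of ``walkers``
    walkers each; ``warmup`` and ``draws`` are counted in kept draws per
    chain; the pooled sample is thinned per chain to at most
    ``max_total`` draws overall."""

    chains: int = 3
    warmup: int = 5000
    draws: int = 5000
    walkers: int = 16
    max_total: int = 10000

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if min(self.warmup, self.draws, self.walkers) < 1:
            raise ValueError("warmup, draws and walkers must be positive")


@dataclass(frozen=True)
class CredibleBand:
    """Pointwise median and 95% band of a predicted quantity."""

    grid: np.ndarray
    q025: np.ndarray
    q50: np.ndarray
    q975: np.ndarray

    def __post_init__(self):
        if not (np.all(self.q025 <= self.q50 + 1e-12) and np.all(self.q50 <= self.q975 + 1e-12)):
            raise ValueError("band quantiles must be ordered")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.grid, "q2.5": self.q025, "median": self.q50, "q97.5": self.q975}
        )


@dataclass(frozen=True)
class PosteriorSample:
    """Joint MCMC draws over a GUTS parameter vector (natural scale)."""

    draws: np.ndarray  # (n_draws, 4)
    param_names: tuple
    model_tag: str
    chain_ids: np.ndarray
    diagnostics: dict
    rng_seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def param_objects(self) -> list:
        cls = SDParams if self.model_tag == "SD" else ITParams
        return [cls(*row) for row in self.draws]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["chain"] = self.chain_ids
        return df

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        return pd.DataFrame(
            np.quantile(self.draws, qs, axis=0).T,
            index=list(self.param_names),
            columns=[f"q{q}" for q in qs],
        )

    def median_params(self) -> GutsParams:
        cls = SDParams if self.model_tag == "SD" else ITParams
        return cls(*np.median(self.draws, axis=0))


# ---------------------------------------------------------------------------
# Likelihood plumbing for the sampler
# ---------------------------------------------------------------------------

def _constant_design_rows(dataset: SurvivalDataset):
    """Flatten a constant-exposure dataset into transition arrays."""
    C, t_prev, t_cur, n_prev, n_cur = [], [], [], [], []
    for s in dataset.series:
        conc = float(s.profile.concentrations[0])
        for i in range(1, s.obs_times.size):
            C.append(conc)
            t_prev.append(s.obs_times[i - 1])
            t_cur.append(s.obs_times[i])
            n_prev.append(s.n_surv[i - 1])
            n_cur.append(s.n_surv[i])
    return tuple(np.asarray(a, dtype=float) for a in (C, t_prev, t_cur, n_prev, n_cur))


def _make_log_prob(dataset: SurvivalDataset, priors: PriorSpec):
    """Vectorised log-posterior over log10-parameter rows."""
    tag = priors.model_tag
    fast = dataset.is_constant
    if fast:
        C, t_prev, t_cur, n_prev, n_cur = _constant_design_rows(dataset)
        surv = sd_survival_constant if tag == "SD" else it_survival_constant

        def loglik_rows(params):  # params (m, 4) natural scale
            a, b, c, d = (params[:, i:i + 1] for i in range(4))
            Sp = surv(a, b, c, d, C[None, :], t_prev[None, :])
            Sc = surv(a, b, c, d, C[None, :], t_cur[None, :])
            p = np.clip(Sc / Sp, 0.0, 1.0)
            return np.sum(_binom_logpmf(n_cur[None, :], n_prev[None, :], p), axis=1)
    else:
        cls = SDParams if tag == "SD" else ITParams

        def loglik_rows(params):
            return np.array([log_likelihood(cls(*row), dataset) for row in params])

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        lp = priors.log_prior(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            out[ok] = lp[ok] + loglik_rows(10.0 ** theta[ok])
        return out

    return log_prob


def _diagnostics(chain_draws: np.ndarray, param_names) -> dict:
    """Split R-hat and bulk ESS per parameter from (chain, draw, dim)."""
    import arviz as az

    rhat, ess = {}, {}
    for i, name in enumerate(param_names):
        arr = chain_draws[:, :, i]  # (chain, draw)
        rhat[name] = float(az.rhat(arr))
        ess[name] = float(az.ess(arr))
    warnings = []
    bad_r = [n for n, v in rhat.items() if v > 1.05]
    bad_e = [n for n, v in ess.items() if v < 100]
    if bad_r:
        warnings.append(f"convergence warning: R-hat > 1.05 for {bad_r}")
    if bad_e:
        warnings.append(f"convergence warning: ESS < 100 for {bad_e}")
    return {"rhat": rhat, "ess": ess, "warnings": warnings}


def fit(
    dataset: SurvivalDataset,
    model_tag: str = "SD",
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> PosteriorSample:
    """Sample the joint posterior of a reduced GUTS model.

    Each chain is an independently seeded emcee ensemble; walkers start
    from the best of 256 prior draws (by log-posterior) plus a small
    jitter, which shortens warmup on peaked likelihoods.
    """
    if priors is None:
        priors = default_priors(dataset, model_tag)
    if priors.model_tag != model_tag:
        raise ValueError("priors were built for a different model")
    mcmc = mcmc or MCMCSettings()
    log_prob = _make_log_prob(dataset, priors)
    names = _PARAM_NAMES[model_tag]
    ndim = len(names)

    chain_seeds = [
        int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for ss in np.random.SeedSequence(seed).spawn(mcmc.chains)
    ]
    keep_steps = math.ceil(mcmc.draws / mcmc.walkers)
    warm_steps = math.ceil(mcmc.warmup / mcmc.walkers)
    per_chain_keep = min(mcmc.draws, mcmc.max_total // mcmc.chains)

    kept, chain_stack = [], []
    # Differential-evolution moves handle the curved k_d/b_w (or k_d/m_w)
    # posterior ridges far better than the default stretch move, which
    # tends to leave walkers stranded in the ridge tails.
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    for cid, cseed in enumerate(chain_seeds):
        rng = np.random.Generator(np.random.PCG64(cseed))
        cand = priors.sample(rng, 256)
        lp = log_prob(cand)
        order = np.argsort(lp)[::-1]
        best = cand[order[:4]]  # tile the best few prior draws across walkers
        p0 = np.tile(best, (math.ceil(mcmc.walkers / best.shape[0]), 1))[: mcmc.walkers]
        p0 = p0 + 0.05 * rng.standard_normal(p0.shape)
        width = priors.log10_bounds
        p0 = np.clip(p0, width[:, 0], width[:, 1])

        sampler = emcee.EnsembleSampler(mcmc.walkers, ndim, log_prob, vectorize=True,
                                        moves=moves)
        sampler.random_state = np.random.RandomState(cseed).get_state()
        sampler.run_mcmc(p0, warm_steps + keep_steps, progress=False)
        chain = sampler.get_chain()[warm_steps:]  # (steps, walkers, ndim)
        flat = chain.reshape(-1, ndim)[-mcmc.draws:]
        idx = np.linspace(0, flat.shape[0] - 1, per_chain_keep).astype(int)
        kept.append(flat[idx])
        chain_stack.append(flat[idx])

    diag = _diagnostics(np.stack(chain_stack), names)
    draws_log10 = np.concatenate(kept)
    chain_ids = np.repeat(np.arange(mcmc.chains), per_chain_keep)
    return PosteriorSample(
        draws=10.0 ** draws_log10,
        param_names=tuple(names),
        model_tag=model_tag,
        chain_ids=chain_ids,
        diagnostics=diag,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Posterior-predictive survival
# ---------------------------------------------------------------------------

def survival_matrix(posterior: PosteriorSample, profile: ExposureProfile, t_grid) -> np.ndarray:
    """S(t) for every posterior draw: (n_draws, len(t_grid))."""
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    d = posterior.draws
    if profile.is_constant:
        conc = float(profile.concentrations[0])
        surv = sd_survival_constant if posterior.model_tag == "SD" else it_survival_constant
        return surv(
            d[:, 0:1], d[:, 1:2], d[:, 2:3], d[:, 3:4], conc, t_grid[None, :]
        )
    return np.vstack([survival(p, profile, t_grid) for p in posterior.param_objects()])


def _mixture_binomial_quantiles(p_matrix: np.ndarray, n: int, qs) -> np.ndarray:
    """Quantiles of the draw-mixture of Binomial(n, p_j) distributions.

    Exact: the mixture pmf over counts 0..n is the mean of the per-draw
    binomial pmfs; each quantile is the smallest count whose mixture CDF
    reaches it.  Shape: (len(qs), p_matrix.shape[1]).
    """
    counts = np.arange(n + 1)
    out = np.empty((len(qs), p_matrix.shape[1]))
    for col in range(p_matrix.shape[1]):
        pm = np.exp(_binom_logpmf(counts[None, :], n, p_matrix[:, col][:, None]))
        cdf = np.cumsum(pm.mean(axis=0))
        for qi, q in enumerate(qs):
            out[qi, col] = counts[np.searchsorted(cdf, q - 1e-12)]
    return out


def predict_survival(
    posterior: PosteriorSample,
    profile: ExposureProfile,
    t_grid,
    mode: str = "rate",
    n_init: int | None = None,
) -> CredibleBand:
    """Median and 95% credible band of predicted survival.

    mode="rate": quantiles of S(t) across draws (type-7 interpolation).
    mode="counts": quantiles of the exact posterior-predictive
    distribution of survivor counts out of ``n_init`` individuals, the
    draw-mixture of Binomial(n_init, S_j(t)).
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    S = survival_matrix(posterior, profile, t_grid)
    if mode == "rate":
        q = np.quantile(S, [0.025, 0.5, 0.975], axis=0)
        return CredibleBand(t_grid, q[0], q[1], q[2])
    if mode == "counts":
        if n_init is None or n_init < 1:
            raise ValueError("counts mode requires n_init >= 1")
        q = _mixture_binomial_quantiles(S, n_init, (0.025, 0.5, 0.975))
        return CredibleBand(t_grid, q[0], q[1], q[2])
    raise ValueError("mode must be 'rate' or 'counts'")


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------

class GUTSModel:
    """Reduced GUTS survival model bound to a dataset.

    Parameters
    ----------
    dataset : SurvivalDataset
        Survival counts with their exposure profiles.
    model : {"SD", "IT"}
        Stochastic-death or individual-tolerance variant.
    priors : PriorSpec, optional
        Defaults to :func:`default_priors` on the dataset.

    Examples
    --------
    >>> res = GUTSModel(dataset, model="SD").fit(seed=1)
    >>> res.summary()
    >>> res.lcx(x=50, t=4)
    """

    def __init__(self, dataset: SurvivalDataset, model: str = "SD",
                 priors: PriorSpec | None = None):
        if model not in _PARAM_NAMES:
            raise ValueError("model must be 'SD' or 'IT'")
        self.dataset = dataset
        self.model_tag = model
        self.priors = priors if priors is not None else default_priors(dataset, model)

    @classmethod
    def from_csv(cls, survival_csv, exposure_csv=None, model: str = "SD", **kw):
        from .io import read_survival_csv

        return cls(read_survival_csv(survival_csv, exposure_csv), model=model, **kw)

    def loglike(self, params: GutsParams) -> float:
        return log_likelihood(params, self.dataset, self.model_tag)

    def fit(self, seed: int = 0, chains: int = 3, warmup: int = 5000,
            draws: int = 5000, walkers: int = 16, max_total: int = 10000) -> "GUTSResults":
        mcmc = MCMCSettings(chains=chains, warmup=warmup, draws=draws,
                            walkers=walkers, max_total=max_total)
        post = fit(self.dataset, self.model_tag, self.priors, mcmc, seed)
        return GUTSResults(self, post)


class GUTSResults:
    """Fit results: the joint posterior plus derived quantities."""

    def __init__(self, model: GUTSModel, posterior: PosteriorSample):
        self.model = model
        self.posterior = posterior

    @property
    def model_tag(self) -> str:
        return self.posterior.model_tag

    def summary(self) -> pd.DataFrame:
        """Posterior medians, 95% credible bounds and diagnostics."""
        q = self.posterior.quantiles()
        q["rhat"] = [self.posterior.diagnostics["rhat"][n] for n in q.index]
        q["ess"] = [self.posterior.diagnostics["ess"][n] for n in q.index]
        return q

    def predict_survival(self, profile, t_grid, mode="rate", n_init=None) -> CredibleBand:
        return predict_survival(self.posterior, profile, t_grid, mode=mode, n_init=n_init)

    def lcx(self, x: float, t: float) -> _endpoints.EndpointEstimate:
        """Posterior LC(x,t) summary (constant-exposure endpoint)."""
        df = _endpoints.endpoint_distribution(
            self.posterior, lambda p, _: _endpoints.lc(p, x, t), [t], endpoint_kind="LC"
        )
        r = df.iloc[0]
        return _endpoints.EndpointEstimate("LC", x, t, r["median"], r["q025"], r["q975"],
                                           self.model_tag)

    def mfx(self, profile: ExposureProfile, x: float, t: float,
            baseline: str = "profile") -> _endpoints.EndpointEstimate:
        """Posterior MF(x,t) summary for a given exposure profile."""
        df = _endpoints.endpoint_distribution(
            self.posterior, lambda p, _: _endpoints.mf(p, profile, x, t, baseline=baseline),
            [t], endpoint_kind="MF",
        )
        r = df.iloc[0]
        return _endpoints.EndpointEstimate("MF", x, t, r["median"], r["q025"], r["q975"],
                                           self.model_tag)

    def depuration_time(self, x: float = 50.0) -> _endpoints.EndpointEstimate:
        """Posterior DRT_x summary (from the k_d marginal)."""
        from .models import depuration_time as _drt

        df = _endpoints.endpoint_distribution(
            self.posterior, lambda p, _: _drt(p.k_d, x), [x], endpoint_kind="DRT"
        )
        r = df.iloc[0]
        return _endpoints.EndpointEstimate("DRT", x, float("nan"), r["median"], r["q025"],
                                           r["q975"], self.model_tag)

    def gof(self, dataset: SurvivalDataset | None = None):
        """Goodness-of-fit report (NRMSE, %PPC, WAIC, LOO-CV).

        Pass a different ``dataset`` for validation: posterior from the
        calibration data, measures on the new data.
        """
        from .gof import gof_report

        return gof_report(self.posterior, dataset or self.model.dataset)
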
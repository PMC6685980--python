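"""Goodness-of-fit measures: NRMSE, %PPC, WAIC and PSIS-LOO-CV.

All four operate on a joint posterior and a survival dataset, which may be
the calibration data or an independent validation set (the cross scheme —
calibrate on constant profiles, score on variable ones, or the reverse —
is a pure data swap at this interface).

The per-observation unit throughout is one count transition
N(t_{i-1}) -> N(t_i), with the conditional-binomial predictive
Binomial(N(t_{i-1}) observed, S(t_i)/S(t_{i-1})) — one-step-ahead
conditioning on the previous *observed* count.

* NRMSE: per posterior draw, the RMSE between observed counts and one
  sampled predictive count per observation (fixed sub-seed), normalised
  by the mean observed count; reported as median and 95% CI over draws.
* %PPC: percentage of observations inside their 95% posterior-predictive
  interval (exact mixture-binomial quantiles); a well-specified fit sits
  near 95%.
* WAIC on the deviance scale: -2 (lppd - p_waic), p_waic the summed
  posterior variance of per-observation log predictive density.
* LOO-CV: leave-one-transition-out expected log predictive density via
  Pareto-smoothed importance sampling, also on the deviance scale; the
  fraction of high Pareto-k observations is attached as a reliability
  diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .inference import PosteriorSample, survival_matrix
from .models import SurvivalDataset, _binom_logpmf

__all__ = ["GofReport", "nrmse", "ppc_percent", "waic", "loo_cv", "gof_report",
           "pointwise_loglik"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GofReport:
    """The four robustness measures for one posterior/dataset pair."""

    nrmse_median: float
    nrmse_q025: float
    nrmse_q975: float
    ppc_pct: float
    waic: float
    loo: float
    n_obs: int
    pareto_k_high_frac: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.ppc_pct <= 100.0):
            raise ValueError("ppc_pct must be in [0, 100]")
        if self.nrmse_median < 0 or not self.nrmse_q025 <= self.nrmse_median <= self.nrmse_q975:
            raise ValueError("NRMSE summary must be non-negative and ordered")

    def to_dict(self) -> dict:
        return {
            "NRMSE": {"median": self.nrmse_median, "q2.5": self.nrmse_q025,
                      "q97.5": self.nrmse_q975},
            "PPC_pct": self.ppc_pct,
            "WAIC": self.waic,
            "LOO": self.loo,
            "n_obs": self.n_obs,
            "pareto_k_high_frac": self.pareto_k_high_frac,
        }


def _transition_tables(posterior: PosteriorSample, dataset: SurvivalDataset):
    """Per-transition arrays: observed previous/current counts and the
    conditional survival probability per draw, stacked over all series.

    Returns (n_prev, n_cur, P) with P of shape (n_draws, n_obs).
    """
    n_prev, n_cur, cols = [], [], []
    for s in dataset.series:
        if s.n_transitions == 0:
            continue
        S = survival_matrix(posterior, s.profile, s.obs_times)
        p = np.clip(S[:, 1:] / S[:, :-1], 0.0, 1.0)
        cols.append(p)
        n_prev.extend(s.n_surv[:-1])
        n_cur.extend(s.n_surv[1:])
    if not cols:
        raise ValueError("dataset has no count transitions")
    return np.asarray(n_prev), np.asarray(n_cur), np.hstack(cols)


def pointwise_loglik(posterior: PosteriorSample, dataset: SurvivalDataset) -> np.ndarray:
    """Log predictive density per draw and per count transition:
    (n_draws, n_obs)."""
    n_prev, n_cur, P = _transition_tables(posterior, dataset)
    return _binom_logpmf(n_cur[None, :], n_prev[None, :], P)


def nrmse(posterior: PosteriorSample, dataset: SurvivalDataset, sub_seed: int = 777):
    """Normalised RMSE distribution over posterior draws.

    For each draw j one predictive count y_{i,j} is sampled per
    observation i (fixed ``sub_seed`` so results are reproducible);
    RMSE_j over observations is divided by the mean observed count.
    Returns (median, q2.5, q97.5) of the NRMSE distribution.
    """
    n_prev, n_cur, P = _transition_tables(posterior, dataset)
    y_mean = float(np.mean(n_cur))
    if y_mean == 0:
        raise ValueError("mean observed count is zero; NRMSE undefined")
    rng = np.random.Generator(np.random.PCG64(sub_seed))
    y_sim = rng.binomial(n_prev[None, :].astype(int), P)
    rmse = np.sqrt(np.mean((y_sim - n_cur[None, :]) ** 2, axis=1))
    nr = rmse / y_mean
    q025, med, q975 = np.quantile(nr, [0.025, 0.5, 0.975])
    return float(med), float(q025), float(q975)


def ppc_percent(posterior: PosteriorSample, dataset: SurvivalDataset) -> float:
    """Percentage of observations inside their 95% predictive interval.

    The predictive for each transition is the exact draw-mixture of
    Binomial(previous observed count, p_j); interval bounds are the
    smallest counts whose mixture CDF reaches 2.5% and 97.5%.
    """
    n_prev, n_cur, P = _transition_tables(posterior, dataset)
    inside = 0
    for i in range(n_cur.size):
        n = int(n_prev[i])
        counts = np.arange(n + 1)
        pm = np.exp(_binom_logpmf(counts[None, :], n, P[:, i][:, None]))
        cdf = np.cumsum(pm.mean(axis=0))
        lo = counts[np.searchsorted(cdf, 0.025 - 1e-12)]
        hi = counts[np.searchsorted(cdf, 0.975 - 1e-12)]
        inside += lo <= n_cur[i] <= hi
    return 100.0 * inside / n_cur.size


def waic(posterior: PosteriorSample, dataset: SurvivalDataset) -> float:
    """WAIC on the deviance scale: -2 (lppd - p_waic).

    lppd_i = log mean_j p(y_i | theta_j); p_waic = sum_i var_j log p.
    A single-draw posterior has zero variance, so WAIC reduces to
    -2 * log-likelihood.
    """
    ll = pointwise_loglik(posterior, dataset)
    m = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(m)
    p_waic = np.var(ll, axis=0, ddof=0) if m > 1 else np.zeros(ll.shape[1])
    return float(-2.0 * (np.sum(lppd) - np.sum(p_waic)))


def loo_cv(posterior: PosteriorSample, dataset: SurvivalDataset,
           k_threshold: float = 0.7):
    """PSIS leave-one-transition-out ELPD on the deviance scale.

    Importance ratios 1/p(y_i|theta_j) are Pareto-smoothed per
    observation; elpd_i = log sum_j w_ij p(y_i|theta_j) with normalised
    smoothed weights.  More than 10% of observations with Pareto
    k > ``k_threshold`` triggers a reliability warning.  With a single
    draw the weights are degenerate and LOO equals -2 * log-likelihood.

    Returns (loo_deviance, pareto_k_high_fraction).
    """
    ll = pointwise_loglik(posterior, dataset)
    if ll.shape[0] == 1:
        return float(-2.0 * np.sum(ll)), 0.0
    from arviz.stats import psislw

    lw, k = psislw(-ll.T)  # smoothing runs along the draw (last) axis
    elpd = logsumexp(lw + ll.T, axis=1)
    frac_high = float(np.mean(k > k_threshold))
    if frac_high > 0.10:
        logger.warning("PSIS-LOO unreliable: %.0f%% of observations have Pareto k > %.2f",
                       100 * frac_high, k_threshold)
    return float(-2.0 * np.sum(elpd)), frac_high


def gof_report(posterior: PosteriorSample, dataset: SurvivalDataset) -> GofReport:
    """All four measures in one report."""
    med, q025, q975 = nrmse(posterior, dataset)
    loo, k_frac = loo_cv(posterior, dataset)
    return GofReport(
        nrmse_median=med,
        nrmse_q025=q025,
        nrmse_q975=q975,
        ppc_pct=ppc_percent(posterior, dataset),
        waic=waic(posterior, dataset),
        loo=loo,
        n_obs=dataset.n_obs,
        pareto_k_high_frac=k_frac,
    )
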
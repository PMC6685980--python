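import numpy as np
import pytest

import gutspy as g


@pytest.fixture(scope="session")
def sd_true():
    """Ground-truth SD parameters used for synthetic experiments."""
    return g.SDParams(k_d=0.8, b_w=0.5, z=2.0, h_b=0.02)


@pytest.fixture(scope="session")
def it_true():
    return g.ITParams(k_d=0.7, m_w=2.0, beta=3.0, h_b=0.02)


@pytest.fixture(scope="session")
def two_pulse_profile():
    return g.make_pulse_profile(2, 4.0, 1.0, [1.0, 5.0], 12.0)


@pytest.fixture(scope="session")
def constant_sd_dataset(sd_true):
    design = g.table1_design("constant", "cypermethrin", threshold=sd_true.z)
    return g.simulate_dataset(sd_true, design, seed=42)


@pytest.fixture(scope="session")
def constant_it_dataset(it_true):
    design = g.table1_design("constant", "cypermethrin", threshold=it_true.m_w)
    return g.simulate_dataset(it_true, design, seed=7)


@pytest.fixture(scope="session")
def sd_results(constant_sd_dataset):
    """One calibrated SD fit shared across inference/GOF/endpoint tests."""
    return g.GUTSModel(constant_sd_dataset, "SD").fit(
        seed=1, chains=3, warmup=3000, draws=1500, walkers=16
    )


@pytest.fixture(scope="session")
def it_results(constant_it_dataset):
    return g.GUTSModel(constant_it_dataset, "IT").fit(
        seed=2, chains=3, warmup=3000, draws=1500, walkers=16
    )


def degenerate_posterior(params, n_draws=5):
    """Posterior whose draws are all the same parameter point."""
    arr = np.tile(params.as_array(), (n_draws, 1))
    return g.PosteriorSample(
        draws=arr,
        param_names=tuple(params.names),
        model_tag="SD" if isinstance(params, g.SDParams) else "IT",
        chain_ids=np.zeros(n_draws, dtype=int),
        diagnostics={"rhat": {}, "ess": {}, "warnings": []},
        rng_seed=0,
    )


def posterior_from_draws(draws, model_tag):
    draws = np.asarray(draws, dtype=float)
    names = g.SDParams.names if model_tag == "SD" else g.ITParams.names
    return g.PosteriorSample(
        draws=draws,
        param_names=tuple(names),
        model_tag=model_tag,
        chain_ids=np.zeros(draws.shape[0], dtype=int),
        diagnostics={"rhat": {}, "ess": {}, "warnings": []},
        rng_seed=0,
    )
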
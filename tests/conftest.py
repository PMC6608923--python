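import numpy as np
import pytest

import sutse


def pytest_configure(config):
    # silence arviz's refactor FutureWarning without hiding package warnings
    import warnings

    warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def toy_c2() -> dict:
    """Small C=2, T=6, q=1 instance with random PD covariances."""
    rng = np.random.default_rng(42)
    spec = sutse.build_model(2, 1)
    corr = sutse.sample_prior_corr(2, 1.0, 2, rng)
    params = sutse.CovParams(
        obs_sd=[0.3, 0.5], obs_corr=corr[0], evo_sd=[0.2, 0.1], evo_corr=corr[1]
    )
    Y = rng.normal(0.0, 1.0, (6, 2))
    data = sutse.ObservedSeries(Y, [f"2007-{m:02d}" for m in range(1, 7)], ["a", "b"])
    return {"spec": spec, "params": params, "data": data, "Y": Y, "init_mean": np.zeros(8)}


def gate_fixture_simulation(seed: int = 11):
    """Well-conditioned C=2, T=120, q=1 simulation used for the convergence gates."""
    spec = sutse.build_model(2, 1)
    params = sutse.CovParams(
        obs_sd=[0.05, 0.05],
        obs_corr=[[1.0, 0.3], [0.3, 1.0]],
        evo_sd=[0.01, 0.01],
        evo_corr=[[1.0, 0.5], [0.5, 1.0]],
    )
    init = np.zeros(spec.state_dim)
    init[0], init[spec.block_dim] = 7.0, 7.5
    init[2], init[spec.block_dim + 2] = 0.1, 0.05
    cfg = sutse.SimulationConfig(
        spec=spec, params=params, init_state=init, n_months=120, seed=seed
    )
    return cfg, sutse.simulate(cfg)


@pytest.fixture(scope="session")
def gate_fixture():
    return gate_fixture_simulation()


def degenerate_posterior(params, series_names, n_draws=10, n_chains=1):
    """PosteriorSamples whose every draw equals the given CovParams."""
    import pandas as pd

    from sutse.inference import MCMCConfig, PosteriorSamples, PriorSpec

    C = len(series_names)
    row = {}
    for k, nm in enumerate(series_names):
        row[f"sigma[{nm}]"] = params.obs_sd[k]
        row[f"gamma[{nm}]"] = params.evo_sd[k]
    for prefix, mat in [("rho_eps", params.obs_corr), ("rho_delta", params.evo_corr)]:
        for i in range(C):
            for j in range(i + 1, C):
                row[f"{prefix}[{series_names[i]},{series_names[j]}]"] = mat[i, j]
    chain = pd.DataFrame([row] * n_draws)
    spec = sutse.build_model(C, 1)
    return PosteriorSamples(
        chains=[chain.copy() for _ in range(n_chains)],
        config=MCMCConfig(n_chains=n_chains, n_warmup=1, n_keep=n_draws, seed=0),
        spec=spec,
        series_names=list(series_names),
        priors=PriorSpec(),
    )


def recovery_config(seed: int) -> sutse.SimulationConfig:
    """C=3, T=120, q=2 with slope-innovation correlation 0.8 between series 0-1."""
    spec = sutse.build_model(3, 2)
    evo_corr = np.eye(3)
    evo_corr[0, 1] = evo_corr[1, 0] = 0.8
    params = sutse.CovParams(
        obs_sd=[0.05] * 3, obs_corr=np.eye(3), evo_sd=[0.01] * 3, evo_corr=evo_corr
    )
    init = np.zeros(spec.state_dim)
    bd = spec.block_dim
    for c in range(3):
        init[c * bd] = 7.0 + 0.3 * c
        init[c * bd + 2], init[c * bd + 3] = 0.08, 0.04
    return sutse.SimulationConfig(
        spec=spec, params=params, init_state=init, n_months=120, seed=seed
    )
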
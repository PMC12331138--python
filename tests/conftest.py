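import numpy as np
import pytest

from transferknock import (
    GaussianDesignModel,
    SimulationConfig,
    generate_environments,
    parse_method,
    run_experiment,
    sample_gaussian_knockoffs,
)

#: desk-scale rendition of the reference multi-environment study design
STUDY = SimulationConfig(
    p=200, n=400, n_env=3, rho=0.5, n_signals=60, amplitude=3.5, q=0.1,
    seed=20260920 % (2**31 - 1),
    gamma_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
)
STUDY_SOLVER = dict(cv_folds=5, n_alphas=30, eps=1e-2)
STUDY_REPS = 100


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale version of the three-environment study design."""
    return SimulationConfig(
        p=40, n=150, n_env=3, rho=0.5, n_signals=8, amplitude=3.5,
        overlap=0.5, q=0.1, seed=101,
    )


@pytest.fixture(scope="session")
def small_envs(small_config):
    """Three small environments with knockoffs attached (read-only)."""
    datasets, truth = generate_environments(small_config, seed=101, rep=0)
    model = GaussianDesignModel.from_ar1(small_config.p, small_config.rho)
    for e, d in enumerate(datasets):
        d.knockoffs = sample_gaussian_knockoffs(d.X, model, 1000 + e).knockoffs
    return datasets, truth, model


@pytest.fixture(scope="session")
def study_summary():
    """Aggregated FDP/power of all methods over 100 replicates per overlap.

    Shared by the FDR-control and power-trend tests; this is the long
    computation of the suite (several minutes).
    """
    methods = [
        parse_method(m)
        for m in (
            "vanilla", "pooling", "lro:0.1", "lro:0.2", "lro:0.4",
            "adaptive:logistic", "wlasso:pooled",
        )
    ]
    summary = run_experiment(
        STUDY, methods, overlap_grid=(0.0, 0.5, 1.0), reps=STUDY_REPS, **STUDY_SOLVER
    )
    return summary.aggregate()
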
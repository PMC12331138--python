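"""Multi-environment synthetic data with controllable support overlap.

Each environment draws covariate rows independently from a shared
zero-mean AR(1) Gaussian law and an outcome from its own sparse linear
model ``y = X beta_e + noise``. All external environments share one
signal set; the fraction of it shared with the target environment's
signal set (the *overlap*) is the control parameter of the power study:
at overlap 1 the external data are maximally informative about the target
support, at overlap 0 they are actively misleading for any method that
pools naively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .gaussian import EnvironmentDataset
from .utils import PURPOSE, child_rng

__all__ = ["SimulationConfig", "TrueModel", "generate_environments", "fdp_power", "ar1_rows"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the multi-environment experiment.

    Defaults are the reference design: three environments of n=800
    observations on p=500 AR(1) (rho=0.5) variables, 60 signals per
    environment with amplitude a=3.5 on the a/sqrt(n) scale, unit
    Gaussian noise, and a nominal FDR level of 10%.
    """

    p: int = 500
    n: int = 800
    n_env: int = 3
    rho: float = 0.5
    n_signals: int = 60
    amplitude: float = 3.5
    amplitude_scale: str = "sqrt_n"  # per-coordinate effect a/sqrt(n) or a/n
    overlap: float = 1.0
    q: float = 0.1
    noise_sd: float = 1.0
    reps: int = 500
    seed: int = 0
    random_signs: bool = False
    theta_grid: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    gamma_grid: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))

    def __post_init__(self) -> None:
        if not 1 <= self.n_signals <= self.p:
            raise ValueError("need 1 <= n_signals <= p")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if self.n_env < 1:
            raise ValueError("need at least one environment")
        if self.amplitude_scale not in ("sqrt_n", "n"):
            raise ValueError("amplitude_scale must be 'sqrt_n' or 'n'")
        shared = self.overlap * self.n_signals
        if abs(shared - round(shared)) > 1e-6:
            raise ValueError(
                f"overlap*n_signals = {shared} is not an integer count of shared signals"
            )
        for g in (self.theta_grid, self.gamma_grid):
            if any(not 0 <= v <= 1 for v in g):
                raise ValueError("grid values must lie in [0, 1]")

    @property
    def n_shared(self) -> int:
        return int(round(self.overlap * self.n_signals))

    @property
    def effect_size(self) -> float:
        denom = np.sqrt(self.n) if self.amplitude_scale == "sqrt_n" else self.n
        return self.amplitude / denom

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_grid"] = list(self.theta_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("theta_grid", "gamma_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TrueModel:
    """Ground truth of one replicate: per-environment supports and effects."""

    supports: list = field(default_factory=list)
    betas: list = field(default_factory=list)

    @property
    def target_support(self) -> np.ndarray:
        return self.supports[0]

    def realized_overlap(self) -> float:
        if len(self.supports) < 2:
            return 1.0
        s0, s1 = set(self.supports[0].tolist()), set(self.supports[1].tolist())
        return len(s0 & s1) / max(len(s0), 1)


def ar1_rows(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. rows of a stationary AR(1) Gaussian vector, built recursively."""
    X = np.empty((n, p))
    X[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1)) * np.sqrt(1 - rho**2)
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + innov[:, j - 1]
    return X


def _draw_supports(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Target support S0 plus one shared external support, at the set overlap."""
    m, k = config.n_signals, config.n_shared
    s_ext = rng.choice(config.p, size=m, replace=False)
    shared = rng.choice(s_ext, size=k, replace=False)
    outside = np.setdiff1d(np.arange(config.p), s_ext, assume_unique=False)
    extra = rng.choice(outside, size=m - k, replace=False)
    s0 = np.sort(np.concatenate([shared, extra]))
    supports = [s0] + [np.sort(s_ext)] * max(config.n_env - 1, 0)
    return supports


def generate_environments(
    config: SimulationConfig, seed: int | None = None, rep: int = 0
) -> tuple[list[EnvironmentDataset], TrueModel]:
    """One multi-environment replicate: datasets plus their ground truth.

    Supports are drawn uniformly at random subject to the overlap
    constraint; nonzero effects all equal ``amplitude / sqrt(n)`` (or
    ``amplitude / n``), optionally with random signs; covariate rows are
    i.i.d. AR(1) Gaussian; outcomes are linear with Gaussian noise.
    Deterministic given ``(seed, rep)``.
    """
    master = config.seed if seed is None else seed
    rng_support = child_rng(master, rep, 0, PURPOSE["support"])
    supports = _draw_supports(config, rng_support)
    eff = config.effect_size
    betas = []
    for e, s in enumerate(supports):
        beta = np.zeros(config.p)
        if config.random_signs:
            signs = child_rng(master, rep, e, PURPOSE["support"] + 100).choice([-1.0, 1.0], size=len(s))
        else:
            signs = 1.0
        beta[s] = eff * signs
        betas.append(beta)
    datasets = []
    for e in range(config.n_env):
        rng_x = child_rng(master, rep, e, PURPOSE["covariates"])
        rng_eps = child_rng(master, rep, e, PURPOSE["noise"])
        X = ar1_rows(config.n, config.p, config.rho, rng_x)
        y = X @ betas[e] + config.noise_sd * rng_eps.standard_normal(config.n)
        datasets.append(EnvironmentDataset(X=X, y=y, env_id=e))
    return datasets, TrueModel(supports=supports, betas=betas)


def fdp_power(selected, true_support) -> tuple[float, float]:
    """False discovery proportion and power of a selection against a truth set."""
    sel = set(np.asarray(selected, dtype=int).tolist())
    truth = set(np.asarray(true_support, dtype=int).tolist())
    fdp = len(sel - truth) / max(len(sel), 1)
    power = len(sel & truth) / max(len(truth), 1)
    return fdp, power
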
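"""Exact model-X knockoffs for multivariate Gaussian covariates.

A knockoff copy ``X~`` of a covariate matrix ``X ~ N(mu, Sigma)`` is a
synthetic negative control: it is built without looking at the outcome and
is exchangeable with the original columns in the joint covariate law, so
that swapping any subset of columns with their knockoffs leaves the joint
distribution unchanged. For Gaussian covariates the construction is exact:
given a diagonal matrix ``S = diag(s)`` with ``2*Sigma - S`` positive
semidefinite, knockoff rows are drawn from the conditional Gaussian

    X~ | X  ~  N( X - (X - mu) Sigma^{-1} S,  2 S - S Sigma^{-1} S ),

which yields the joint covariance ``[[Sigma, Sigma - S], [Sigma - S,
Sigma]]``. Larger ``s`` entries decorrelate knockoffs from originals and
increase power downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .utils import PURPOSE, child_rng

__all__ = [
    "GaussianDesignModel",
    "EnvironmentDataset",
    "AugmentedDesign",
    "ar1_covariance",
    "solve_equicorrelated_s",
    "sample_gaussian_knockoffs",
]

#: multiplicative slack applied to the knockoff diagonal so that
#: 2*Sigma - diag(s) stays PSD under floating point.
S_SLACK = 1.0 - 1e-6

#: refuse covariance matrices more ill-conditioned than this.
MAX_CONDITION = 1e10


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """Covariance of a stationary first-order autoregressive process.

    Entry (i, j) is ``rho ** |i - j|`` with unit diagonal; positive
    definite for ``|rho| < 1``.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if not abs(rho) < 1:
        raise ValueError(f"AR(1) parameter must satisfy |rho| < 1, got {rho}")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _check_covariance(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 0:
        raise ValueError(f"covariance must be positive definite (lambda_min={eig[0]:.3e})")
    if eig[-1] / eig[0] > MAX_CONDITION:
        raise ValueError(
            f"covariance condition number {eig[-1] / eig[0]:.2e} exceeds {MAX_CONDITION:.0e}; "
            "refusing to invert"
        )
    return cov


def solve_equicorrelated_s(covariance: np.ndarray) -> np.ndarray:
    """Equicorrelated knockoff diagonal ``s = min(1, 2 lambda_min) * ones``.

    Assumes a correlation-scale covariance (unit diagonal); standardize
    first otherwise. The constant is shrunk by a tiny slack factor so the
    PSD constraint on ``2*Sigma - diag(s)`` survives floating point.
    """
    cov = _check_covariance(covariance)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    s_val = min(1.0, 2.0 * lam_min) * S_SLACK
    return np.full(cov.shape[0], s_val)


@dataclass
class GaussianDesignModel:
    """Gaussian covariate law plus the knockoff diagonal that defines the sampler.

    Parameters
    ----------
    mean : (p,) array
        Covariate mean.
    covariance : (p, p) array
        Symmetric positive-definite covariance.
    s_diag : (p,) array
        Knockoff diagonal; ``2*covariance - diag(s_diag)`` must be PSD.
    rho : float, optional
        Records the AR(1) parameter when the covariance is AR(1).
    """

    mean: np.ndarray
    covariance: np.ndarray
    s_diag: np.ndarray
    rho: float | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = _check_covariance(self.covariance)
        self.s_diag = np.asarray(self.s_diag, dtype=float)
        p = self.covariance.shape[0]
        if self.mean.shape != (p,) or self.s_diag.shape != (p,):
            raise ValueError("mean and s_diag must be length-p vectors")
        if np.any(self.s_diag < 0) or np.any(self.s_diag > 2 * np.diag(self.covariance)):
            raise ValueError("s_diag entries must lie in [0, 2*diag(covariance)]")
        slack = 2 * self.covariance - np.diag(self.s_diag)
        if np.linalg.eigvalsh(slack)[0] < -1e-8:
            raise ValueError("2*covariance - diag(s_diag) must be positive semidefinite")

    @property
    def p(self) -> int:
        return self.covariance.shape[0]

    @classmethod
    def from_ar1(cls, p: int, rho: float) -> "GaussianDesignModel":
        """Zero-mean AR(1) design with the equicorrelated knockoff diagonal."""
        cov = ar1_covariance(p, rho)
        return cls(mean=np.zeros(p), covariance=cov, s_diag=solve_equicorrelated_s(cov), rho=rho)

    @classmethod
    def from_covariance(cls, covariance: np.ndarray, mean: np.ndarray | None = None,
                        s_diag: np.ndarray | None = None) -> "GaussianDesignModel":
        covariance = _check_covariance(covariance)
        p = covariance.shape[0]
        if mean is None:
            mean = np.zeros(p)
        if s_diag is None:
            d = np.sqrt(np.diag(covariance))
            corr = covariance / np.outer(d, d)
            s_diag = solve_equicorrelated_s(corr) * d**2
        return cls(mean=mean, covariance=covariance, s_diag=s_diag)


@dataclass
class EnvironmentDataset:
    """One environment's design matrix and outcome.

    ``env_id`` 0 is the target environment of the analysis; positive ids
    label external environments whose data inform but are not tested.
    """

    X: np.ndarray
    y: np.ndarray
    env_id: int = 0
    knockoffs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if self.y.shape != (n,):
            raise ValueError(f"y length {self.y.shape[0]} does not match n={n}")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("X and y must be finite with no missing values")
        if self.knockoffs is not None:
            self.knockoffs = np.asarray(self.knockoffs, dtype=float)
            if self.knockoffs.shape != self.X.shape:
                raise ValueError("knockoffs must match the shape of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def augmented(self) -> "AugmentedDesign":
        if self.knockoffs is None:
            raise ValueError(f"environment {self.env_id} carries no knockoffs")
        return AugmentedDesign(np.hstack([self.X, self.knockoffs]))


@dataclass
class AugmentedDesign:
    """An n x 2p design whose column j pairs with its knockoff at column j+p."""

    XXt: np.ndarray

    def __post_init__(self) -> None:
        self.XXt = np.asarray(self.XXt, dtype=float)
        if self.XXt.ndim != 2 or self.XXt.shape[1] % 2 != 0:
            raise ValueError("augmented design must have an even number of columns")

    @property
    def n(self) -> int:
        return self.XXt.shape[0]

    @property
    def p(self) -> int:
        return self.XXt.shape[1] // 2

    @property
    def originals(self) -> np.ndarray:
        return self.XXt[:, : self.p]

    @property
    def knockoffs(self) -> np.ndarray:
        return self.XXt[:, self.p:]

    def swapped(self, subset) -> "AugmentedDesign":
        """Exchange columns j and j+p for every j in ``subset`` (0-based)."""
        out = self.XXt.copy()
        idx = np.asarray(list(subset), dtype=int)
        out[:, idx], out[:, idx + self.p] = (
            self.XXt[:, idx + self.p].copy(),
            self.XXt[:, idx].copy(),
        )
        return AugmentedDesign(out)


def sample_gaussian_knockoffs(
    X: np.ndarray, model: GaussianDesignModel, seed: int
) -> AugmentedDesign:
    """Draw exact Gaussian knockoffs for each row of ``X``.

    Rows of the knockoff block are sampled independently from the
    conditional law ``N(X - (X - mu) Sigma^{-1} S, 2S - S Sigma^{-1} S)``;
    the draw is deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.p:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, model expects {model.p}"
        )
    Sigma = model.covariance
    s = model.s_diag
    # Sigma^{-1} S by Cholesky solve; S Sigma^{-1} S is symmetric PSD.
    cho = linalg.cho_factor(Sigma, lower=True)
    inv_times_S = linalg.cho_solve(cho, np.diag(s))
    cond_mean = X - (X - model.mean) @ inv_times_S
    cond_cov = 2 * np.diag(s) - np.diag(s) @ inv_times_S
    cond_cov = (cond_cov + cond_cov.T) / 2
    # eigendecomposition handles the degenerate s -> 0 limit (zero variance)
    eigval, eigvec = np.linalg.eigh(cond_cov)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = child_rng(seed, PURPOSE["knockoffs"])
    Z = rng.standard_normal(X.shape)
    return AugmentedDesign(np.hstack([X, cond_mean + Z @ root.T]))
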
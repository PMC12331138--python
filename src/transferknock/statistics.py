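"""Flip-sign importance statistics from sparse regression on augmented designs.

The statistic for variable j is ``W_j = |b_j| - |b_{j+p}|`` where ``b`` are
the coefficients of an l1-penalized regression of the outcome on the
standardized augmented design ``[X, X~]``. A large positive ``W_j`` says
the original column explains the outcome much better than its knockoff;
under the null the two are exchangeable and the sign of ``W_j`` is a fair
coin flip. The prior-informed variant penalizes each original/knockoff
pair with its own strength, derived from coefficients fitted on external
data: promising variables (small penalty weight ``phi_j``) are regularized
less, which concentrates the model on them and sharpens the statistics
without breaking the flip-sign symmetry, because the weight is shared
within each pair.

Per-feature penalties are realized exactly through the column-rescaling
equivalence (divide column j by its relative penalty factor, solve a
single-penalty lasso, scale the coefficient back), so one coordinate
descent solver serves both constructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.model_selection import KFold

from .gaussian import AugmentedDesign, EnvironmentDataset
from .utils import PURPOSE, child_int, child_rng, standardize_columns

__all__ = [
    "StatisticVector",
    "PriorInformation",
    "lasso_coefdiff_stats",
    "weighted_lasso_stats",
    "prior_weights_from_coefficients",
    "pooled_coefficients",
    "combine_multi_priors",
]

#: additive offset in the prior-weight formula phi = 1/(eps + |b| + |b_knock|)
DEFAULT_PHI_EPS = 0.05

_LASSO_TOL = 1e-4
_LASSO_MAX_ITER = 10000


@dataclass
class StatisticVector:
    """Length-p knockoff statistics with the tuning actually used."""

    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float).ravel()
        if not np.isfinite(self.W).all():
            raise ValueError("statistics must be finite")

    def __len__(self) -> int:
        return len(self.W)


@dataclass
class PriorInformation:
    """External information attached to each variable/knockoff pair.

    At least one of ``coef_ext`` (length-2p fitted external coefficients),
    ``stat_ext`` (length-p external knockoff statistics) or ``multi``
    (p x K matrix of prior statistic columns) must be present. ``phi``
    holds the derived penalty weights, one per pair (implicitly symmetric).
    """

    coef_ext: np.ndarray | None = None
    stat_ext: np.ndarray | None = None
    phi: np.ndarray | None = None
    multi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coef_ext is None and self.stat_ext is None and self.multi is None:
            raise ValueError("at least one of coef_ext, stat_ext, multi must be given")
        for name in ("coef_ext", "stat_ext", "phi"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).ravel())
        if self.multi is not None:
            self.multi = np.atleast_2d(np.asarray(self.multi, dtype=float))
        if self.phi is not None and (np.any(self.phi <= 0) or not np.isfinite(self.phi).all()):
            raise ValueError("phi entries must be strictly positive and finite")

    def prior_columns(self) -> np.ndarray:
        """The p x K matrix of prior statistic columns for ordering models."""
        if self.multi is not None:
            return self.multi
        if self.stat_ext is not None:
            return self.stat_ext[:, None]
        raise ValueError("no prior statistic columns available (only coefficients)")


def prior_weights_from_coefficients(
    coef_ext: np.ndarray, eps: float = DEFAULT_PHI_EPS, include_knockoffs: bool = True
) -> np.ndarray:
    """Inverse prior-importance weights ``phi_j = 1/(eps + |b_j| + |b_{j+p}|)``.

    ``coef_ext`` stacks p original coefficients then their p knockoff
    coefficients. Setting ``include_knockoffs=False`` drops the knockoff
    term, an equally valid simpler weight. Smaller ``phi`` marks a more
    promising variable; the returned length-p vector applies symmetrically
    to both members of each pair.
    """
    b = np.asarray(coef_ext, dtype=float).ravel()
    if not np.isfinite(b).all():
        raise ValueError("external coefficients must be finite")
    if b.size % 2 != 0:
        raise ValueError(f"coefficient vector length must be even (2p), got {b.size}")
    p = b.size // 2
    denom = eps + np.abs(b[:p])
    if include_knockoffs:
        denom = denom + np.abs(b[p:])
    return 1.0 / denom


def combine_multi_priors(coef_list) -> np.ndarray:
    """Entrywise mean of several external coefficient vectors."""
    if len(coef_list) == 0:
        raise ValueError("need at least one coefficient vector")
    arrs = [np.asarray(c, dtype=float).ravel() for c in coef_list]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("coefficient vectors must share one length")
    return np.mean(arrs, axis=0)


def _check_design_outcome(design: AugmentedDesign, y) -> tuple[np.ndarray, np.ndarray, int]:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != design.n:
        raise ValueError(f"outcome length {y.shape[0]} does not match n={design.n}")
    if np.std(y) == 0:
        raise ValueError("outcome is constant; statistics are undefined")
    return standardize_columns(design.XXt), y, design.p


def _swap_mask(p: int, seed: int) -> np.ndarray:
    # Random within-pair swaps symmetrize any residual solver-order bias:
    # columns j and j+p are exchanged before the fit wherever the mask is
    # set and the statistic sign is flipped back afterwards, which leaves
    # non-null statistics untouched and makes null signs exactly symmetric.
    return child_rng(seed, PURPOSE["column_swap"]).random(p) < 0.5


def _apply_swap(Z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    p = mask.size
    out = Z.copy()
    idx = np.flatnonzero(mask)
    out[:, idx], out[:, idx + p] = Z[:, idx + p].copy(), Z[:, idx].copy()
    return out


def _coefdiff(coef: np.ndarray, p: int, mask: np.ndarray) -> np.ndarray:
    W = np.abs(coef[:p]) - np.abs(coef[p:])
    W[mask] *= -1.0
    return W


def _cv_folds(n: int, cv_folds: int, seed: int) -> list:
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if n < cv_folds:
        raise ValueError(f"n={n} is smaller than cv_folds={cv_folds}")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=child_int(seed, PURPOSE["cv_folds"]))
    return list(kf.split(np.empty((n, 1))))


def lasso_coefdiff_stats(
    design: AugmentedDesign,
    y,
    cv_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_alphas: int = 100,
    eps: float = 1e-3,
    tol: float = _LASSO_TOL,
    family: str = "gaussian",
    random_swap: bool = True,
) -> StatisticVector:
    """Lasso coefficient-difference statistics ``W_j = |b_j| - |b_{j+p}|``.

    The penalty is tuned by seeded K-fold cross-validation unless a fixed
    ``alpha`` is given (in scikit-learn's 1/(2n) scaling). ``family`` may
    be ``"gaussian"`` (least squares, default) or ``"binomial"`` (l1
    logistic regression for binary outcomes).
    """
    Z, y, p = _check_design_outcome(design, y)
    mask = _swap_mask(p, seed) if random_swap else np.zeros(p, dtype=bool)
    Zs = _apply_swap(Z, mask)
    if family == "binomial":
        coef, used_alpha = _fit_logistic_l1(Zs, y, alpha, cv_folds, seed)
    elif family == "gaussian":
        coef, used_alpha = _fit_lasso(Zs, y, alpha, cv_folds, seed, n_alphas, eps, tol)
    else:
        raise ValueError(f"unknown family {family!r}")
    return StatisticVector(
        _coefdiff(coef, p, mask),
        meta={"method": "lasso_coefdiff", "alpha": used_alpha, "family": family},
    )


def _fit_lasso(Z, y, alpha, cv_folds, seed, n_alphas,
               eps=1e-3, tol=_LASSO_TOL) -> tuple[np.ndarray, float]:
    if alpha is not None:
        model = Lasso(alpha=alpha, fit_intercept=True, tol=tol,
                      precompute=True, max_iter=_LASSO_MAX_ITER)
        model.fit(Z, y)
        return model.coef_, float(alpha)
    folds = _cv_folds(len(y), cv_folds, seed)
    cv = LassoCV(alphas=n_alphas, eps=eps, cv=folds, fit_intercept=True,
                 tol=tol, precompute=True, max_iter=_LASSO_MAX_ITER)
    cv.fit(Z, y)
    return cv.coef_, float(cv.alpha_)


def _fit_logistic_l1(Z, y, alpha, cv_folds, seed) -> tuple[np.ndarray, float]:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binomial family requires a binary outcome")
    n = len(y)
    if alpha is None:
        # small grid of C values by seeded CV error
        folds = _cv_folds(n, cv_folds, seed)
        grid = np.logspace(-2, 2, 10)
        scores = []
        for C in grid:
            acc = 0.0
            for tr, te in folds:
                m = LogisticRegression(l1_ratio=1, C=C, solver="liblinear", max_iter=2000)
                m.fit(Z[tr], y[tr])
                acc += m.score(Z[te], y[te])
            scores.append(acc / len(folds))
        C = float(grid[int(np.argmax(scores))])
    else:
        C = 1.0 / (2 * n * alpha)
    m = LogisticRegression(l1_ratio=1, C=C, solver="liblinear", max_iter=5000)
    m.fit(Z, y)
    return m.coef_.ravel(), 1.0 / (2 * n * C)


def weighted_lasso_stats(
    design: AugmentedDesign,
    y,
    phi: np.ndarray,
    gamma_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    eps: float = 1e-3,
    tol: float = _LASSO_TOL,
    fixed: tuple[float, float] | None = None,
    random_swap: bool = True,
) -> StatisticVector:
    """Prior-weighted lasso statistics with pairwise-symmetric penalties.

    For mixing weight gamma the relative penalty factor of pair j is
    ``f_j = (1 - gamma) + gamma * phi_j``, normalized to unit mean so the
    cross-validated base penalty lives on a comparable scale for every
    gamma; the per-feature penalty is ``lambda_j = lambda * f_j /
    mean(f)`` applied identically to columns j and j+p. The (lambda,
    gamma) pair minimizing cross-validated squared error on the target
    data is selected, with ties broken toward smaller gamma (less reliance
    on the prior) and then larger lambda (sparser model). ``gamma = 0``
    recovers the unweighted statistics exactly.

    ``fixed=(lam, gamma)`` skips cross-validation and fits at that pair.
    """
    Z, y, p = _check_design_outcome(design, y)
    phi = np.asarray(phi, dtype=float).ravel()
    if phi.shape != (p,):
        raise ValueError(f"phi must have length p={p}, got {phi.shape}")
    if np.any(phi <= 0) or not np.isfinite(phi).all():
        raise ValueError("phi entries must be strictly positive and finite")
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    gamma_grid = np.asarray(gamma_grid, dtype=float).ravel()
    if len(gamma_grid) == 0 or np.any((gamma_grid < 0) | (gamma_grid > 1)):
        raise ValueError("gamma grid must be non-empty with values in [0, 1]")

    mask = _swap_mask(p, seed) if random_swap else np.zeros(p, dtype=bool)
    Zs = _apply_swap(Z, mask)

    if fixed is not None:
        lam, gamma = fixed
        coef = _weighted_fit(Zs, y, phi, gamma, lam, tol)
        return StatisticVector(
            _coefdiff(coef, p, mask),
            meta={"method": "weighted_lasso", "lambda": float(lam), "gamma": float(gamma)},
        )

    folds = _cv_folds(len(y), cv_folds, seed)
    best = None  # (mse, gamma, lam)
    for gamma in gamma_grid:
        Zg = Zs / np.tile(_penalty_factors(phi, gamma), 2)[None, :]
        cv = LassoCV(alphas=n_alphas, eps=eps, cv=folds, fit_intercept=True,
                     tol=tol, precompute=True, max_iter=_LASSO_MAX_ITER)
        cv.fit(Zg, y)
        mean_mse = cv.mse_path_.mean(axis=1)
        i = int(np.argmin(mean_mse))
        # among ties on the path prefer the larger alpha (sparser); the
        # path is sorted descending so argmin already picks it
        cand = (float(mean_mse[i]), float(gamma), float(cv.alphas_[i]))
        if best is None or _better(cand, best):
            best = cand
    _, gamma, lam = best
    coef = _weighted_fit(Zs, y, phi, gamma, lam, tol)
    return StatisticVector(
        _coefdiff(coef, p, mask),
        meta={"method": "weighted_lasso", "lambda": lam, "gamma": gamma, "cv_mse": best[0]},
    )


def _better(cand, best) -> bool:
    """CV-error comparison with ties toward smaller gamma, then larger lambda."""
    mse_c, g_c, l_c = cand
    mse_b, g_b, l_b = best
    if not np.isclose(mse_c, mse_b, rtol=1e-10, atol=1e-12):
        return mse_c < mse_b
    if g_c != g_b:
        return g_c < g_b
    return l_c > l_b


def _penalty_factors(phi: np.ndarray, gamma: float) -> np.ndarray:
    f = (1.0 - gamma) + gamma * phi
    return f / f.mean()


def _weighted_fit(Z, y, phi, gamma, lam, tol=_LASSO_TOL) -> np.ndarray:
    """Exact per-feature-penalty lasso via the column-rescaling equivalence."""
    f2 = np.tile(_penalty_factors(phi, gamma), 2)
    model = Lasso(alpha=lam, fit_intercept=True, tol=tol,
                  precompute=True, max_iter=_LASSO_MAX_ITER)
    model.fit(Z / f2[None, :], y)
    return model.coef_ / f2


def pooled_coefficients(
    datasets: list[EnvironmentDataset],
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    eps: float = 1e-3,
    tol: float = _LASSO_TOL,
) -> np.ndarray:
    """Cross-validated lasso coefficients on row-concatenated environments.

    Every dataset must carry its own knockoffs; the pooled augmented
    design is standardized as a whole before fitting. Cross-validation
    folds are assigned per environment from ``(seed, env_id)``, so the
    result does not depend on the order in which datasets are listed.
    Returns the length-2p coefficient vector (originals then knockoffs)
    used to build prior weights.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset to pool")
    ps = {d.p for d in datasets}
    if len(ps) != 1:
        raise ValueError(f"datasets disagree on p: {sorted(ps)}")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    blocks = [d.augmented.XXt for d in datasets]
    Z = standardize_columns(np.vstack(blocks))
    y = np.concatenate([d.y for d in datasets])
    labels = np.concatenate(
        [
            child_rng(seed, PURPOSE["cv_folds"], d.env_id).permutation(
                np.arange(d.n) % cv_folds
            )
            for d in datasets
        ]
    )
    folds = [
        (np.flatnonzero(labels != k), np.flatnonzero(labels == k))
        for k in range(cv_folds)
    ]
    cv = LassoCV(alphas=n_alphas, eps=eps, cv=folds, fit_intercept=True,
                 tol=tol, precompute=True, max_iter=_LASSO_MAX_ITER)
    cv.fit(Z, y)
    return cv.coef_
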
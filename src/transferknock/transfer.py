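"""Ordering-based transfer learning for the knockoff filter.

Two ways to spend external information without touching FDR control:

* **Linear re-ordering** keeps the target statistics' signs but replaces
  their magnitudes by a convex combination ``(1-theta)|W0| + theta|Wext|``
  of the target and external magnitudes. Null signs stay fair coin flips
  because the external statistics are computed on independent data, so the
  standard threshold filter applies unchanged.

* **The adaptive knockoff filter** keeps ``W0`` itself but learns the
  hypothesis ordering: starting with every sign masked, it repeatedly fits
  a sign-prediction model on the already-revealed hypotheses (covariates:
  the masked magnitude ``|W0_j|`` and the fully-observed prior columns)
  and reveals next the hypothesis deemed most likely to carry a negative
  sign. Positives therefore pile up at the end of the testing sequence,
  which is where the sequential filter keeps them. Validity only needs the
  choice of the next reveal to ignore unrevealed signs (sign invariance),
  which the masking enforces by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filter import FilterConfig, SelectionResult, sequential_filter
from .statistics import PriorInformation, StatisticVector

__all__ = [
    "linear_reorder",
    "adaptive_filter",
    "OrderingState",
    "FixedLinearModel",
    "LogisticSignModel",
]


def linear_reorder(W0, Wext, theta: float) -> StatisticVector:
    """Linearly re-ordered statistics: target signs, blended magnitudes.

    ``sign(W_lro) = sign(W0)`` and ``|W_lro| = (1-theta)|W0| +
    theta|Wext|``; a zero target statistic stays zero. ``theta`` must be
    chosen before looking at the data for the FDR guarantee to hold.
    """
    if not 0 <= theta <= 1:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    w0 = np.asarray(getattr(W0, "W", W0), dtype=float).ravel()
    wext = np.asarray(getattr(Wext, "W", Wext), dtype=float).ravel()
    if w0.shape != wext.shape:
        raise ValueError("W0 and Wext must have equal length")
    mag = (1 - theta) * np.abs(w0) + theta * np.abs(wext)
    return StatisticVector(np.sign(w0) * mag, meta={"method": "linear_reorder", "theta": theta})


@dataclass
class OrderingState:
    """Trace of an adaptive ordering run.

    ``reveal_order`` lists hypotheses in the order their signs were
    revealed (position 0 = first revealed = tested first); each ``trace``
    entry records (step, hypothesis, model label, coefficients or None).
    """

    reveal_order: np.ndarray
    trace: list = field(default_factory=list)


class FixedLinearModel:
    """Static negativity score ``-((1-theta)|W0_j| + theta*|prior|_j)``.

    A small blended magnitude marks a hypothesis as unpromising, hence
    most likely to carry a negative (null) sign; those are revealed first.
    With this model the adaptive filter reduces to the sequential filter
    applied to the static ordering by ascending blended magnitude.
    """

    name = "fixed_linear"
    needs_refit = False

    def __init__(self, theta: float = 0.5):
        if not 0 <= theta <= 1:
            raise ValueError(f"theta must lie in [0, 1], got {theta}")
        self.theta = theta

    def score(self, abs_w0: np.ndarray, priors: np.ndarray,
              revealed_idx: np.ndarray, revealed_neg: np.ndarray) -> np.ndarray:
        prior_mag = np.abs(priors).mean(axis=1)
        return -((1 - self.theta) * abs_w0 + self.theta * prior_mag)


class LogisticSignModel:
    """Iteratively refit logistic model for P(sign(W0_j) = -1).

    Covariates are ``(|W0_j|, prior columns)``; the fit uses only the
    revealed hypotheses with a genuine sign (zero statistics carry no
    sign information and are excluded from training). Two safeguards
    address the selective nature of the training sample — hypotheses are
    revealed precisely because they looked negative, so the magnitude
    coefficient is weakly identified early on:

    * the coefficient on ``|W0_j|`` is constrained nonpositive, so when
      the priors carry no signal the learned ordering degenerates to the
      ascending-magnitude ordering of the standard filter instead of an
      arbitrary one;
    * the prior coefficients get a stronger ridge penalty
      (``ridge_prior``) than the magnitude coefficient (``ridge_mag``),
      shrinking the prior's influence toward zero unless the revealed
      signs support it. The penalty is fixed while the training set
      grows, so the shrinkage fades as evidence accumulates.

    Degenerate fits (fewer than two informative reveals, or all revealed
    signs equal) fall back to the fixed-linear score and are flagged in
    the trace.
    """

    name = "logistic"
    needs_refit = True

    def __init__(self, ridge_mag: float = 1.0, ridge_prior: float = 10.0,
                 fallback_theta: float = 0.5):
        self.ridge_mag = ridge_mag
        self.ridge_prior = ridge_prior
        self.fallback = FixedLinearModel(fallback_theta)
        self.last_coef_: np.ndarray | None = None
        self.fell_back_: bool = False

    def _fit(self, F: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Ridge-penalized MLE with the magnitude coefficient bounded <= 0."""
        from scipy.optimize import minimize

        m, k = F.shape
        X = np.column_stack([F, np.ones(m)])
        pen = np.array([self.ridge_mag] + [self.ridge_prior] * (k - 1) + [0.0])
        s = 2.0 * labels - 1.0  # +1 = negative statistic

        def nll(th):
            eta = X @ th
            val = np.logaddexp(0.0, -s * eta).sum() + 0.5 * np.sum(pen * th**2)
            grad = -(s / (1.0 + np.exp(s * eta))) @ X + pen * th
            return val, grad

        bounds = [(None, 0.0)] + [(None, None)] * k
        res = minimize(nll, np.zeros(k + 1), jac=True, method="L-BFGS-B", bounds=bounds)
        return res.x

    def score(self, abs_w0, priors, revealed_idx, revealed_neg):
        features = np.column_stack([abs_w0, priors])
        informative = abs_w0[revealed_idx] > 0
        idx = revealed_idx[informative]
        labels = revealed_neg[informative]
        self.fell_back_ = False
        self.last_coef_ = None
        if len(idx) < 2 or len(np.unique(labels)) < 2:
            self.fell_back_ = True
            return self.fallback.score(abs_w0, priors, revealed_idx, revealed_neg)
        theta = self._fit(features[idx], labels)
        self.last_coef_ = theta
        # pin the magnitude coefficient strictly negative so ordering ties
        # resolve toward ascending |W0| rather than arbitrarily
        theta = theta.copy()
        theta[0] = min(theta[0], -1e-8)
        return np.column_stack([features, np.ones(len(features))]) @ theta


def _resolve_model(model):
    if isinstance(model, str):
        if model == "logistic":
            return LogisticSignModel()
        if model == "fixed_linear":
            return FixedLinearModel()
        raise ValueError(f"unknown ordering model {model!r}")
    if model is None:
        return LogisticSignModel()
    if not hasattr(model, "score"):
        raise TypeError("ordering model must expose a .score(...) method")
    return model


def adaptive_filter(
    W0,
    priors: PriorInformation,
    config: FilterConfig = FilterConfig(),
    model="logistic",
    batch: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Adaptive knockoff filter with a data-driven hypothesis ordering.

    Builds the ordering by revealing, in batches of ``batch``, the
    hypotheses most likely to carry negative signs according to the sign
    model (refit after every batch on the revealed signs); the completed
    ordering is passed to the sequential filter. The first ``2*batch``
    reveals always use the uninformed fixed-linear score, after which the
    requested model takes over. The returned result carries the full
    :class:`OrderingState` trace.
    """
    if batch < 1:
        raise ValueError(f"batch must be >= 1, got {batch}")
    w0 = np.asarray(getattr(W0, "W", W0), dtype=float).ravel()
    p = len(w0)
    prior_cols = priors.prior_columns()
    if prior_cols.shape[0] != p:
        raise ValueError(
            f"prior columns have {prior_cols.shape[0]} rows, expected p={p}"
        )
    sign_model = _resolve_model(model)
    warmup = FixedLinearModel(0.5)
    abs_w0 = np.abs(w0)
    neg_label = (w0 < 0).astype(int)  # zeros count as non-negative labels

    reveal_order = np.empty(p, dtype=int)
    remaining = np.ones(p, dtype=bool)
    trace: list = []
    scores = None
    for k in range(p):
        refit_due = scores is None or (sign_model.needs_refit and k % batch == 0)
        if refit_due:
            revealed_idx = reveal_order[:k]
            active = warmup if (sign_model.needs_refit and k < 2 * batch) else sign_model
            scores = active.score(abs_w0, prior_cols, revealed_idx, neg_label[revealed_idx])
            coef = getattr(active, "last_coef_", None)
            label = active.name
            if getattr(active, "fell_back_", False):
                label = f"{active.name}:fallback"
            trace.append((k, label, None if coef is None else coef.copy()))
        # stable argmax over remaining: ties broken by original index
        masked = np.where(remaining, scores, -np.inf)
        nxt = int(np.argmax(masked))
        reveal_order[k] = nxt
        remaining[nxt] = False

    result = sequential_filter(w0, reveal_order, config)
    result.trace = OrderingState(reveal_order=reveal_order.copy(), trace=trace)
    return result
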
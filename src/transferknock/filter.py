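"""The knockoff filter: statistics in, FDR-controlled rejection set out.

Two equivalent formulations are provided. The threshold form picks the
smallest t > 0 with

    (offset + #{j: W_j <= -t}) / max(#{j: W_j >= t}, 1)  <=  q

and rejects every W_j >= t. The sequential form sorts the hypotheses by a
given ordering, finds the smallest step k at which the estimated false
discovery proportion among the not-yet-dropped hypotheses falls below q,
and rejects the positive statistics past that step. With the ordering by
ascending |W| the two forms coincide; with a data-adaptive ordering the
sequential form is the adaptive knockoff filter.

Zero statistics count as neither positive nor negative and are never
rejected. ``offset=1`` gives provable FDR control; ``offset=0`` is more
powerful but loses the guarantee when very few discoveries are made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterConfig",
    "SelectionResult",
    "knockoff_threshold",
    "sequential_filter",
    "ascending_magnitude_order",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Nominal FDR level ``q`` and the numerator offset (0 or 1)."""

    q: float = 0.1
    offset: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must lie strictly in (0, 1), got {self.q}")
        if self.offset not in (0, 1):
            raise ValueError(f"offset must be 0 or 1, got {self.offset}")
        if self.offset == 0:
            logger.warning(
                "offset=0 does not theoretically control the FDR when the "
                "number of discoveries is very small"
            )


@dataclass
class SelectionResult:
    """Outcome of a knockoff filter run.

    ``selected`` holds 0-based variable indices; ``threshold`` is the
    selection threshold (+inf when nothing is rejected); ``fdphat_path``
    records the estimated-FDP trace over the evaluated steps; ``ordering``
    is the hypothesis ordering actually used (0-based permutation);
    ``stop_step`` is the stopping index k of the sequential form.
    """

    selected: np.ndarray
    threshold: float
    fdphat_path: np.ndarray
    ordering: np.ndarray
    stop_step: int | None = None
    trace: object = field(default=None, repr=False)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _as_w(W) -> np.ndarray:
    arr = np.asarray(getattr(W, "W", W), dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError("knockoff statistics must be finite")
    return arr


def ascending_magnitude_order(W) -> np.ndarray:
    """Stable ordering of hypotheses by ascending |W| (ties by index)."""
    w = _as_w(W)
    return np.argsort(np.abs(w), kind="stable")


def knockoff_threshold(W, config: FilterConfig = FilterConfig()) -> SelectionResult:
    """Threshold form of the knockoff filter.

    Scans the candidate thresholds {|W_j| : W_j != 0} in ascending order
    and stops at the first whose estimated FDP is at or below q; returns
    the empty set (threshold +inf) if none qualifies.
    """
    w = _as_w(W)
    candidates = np.unique(np.abs(w[w != 0]))
    fdphat = np.empty(len(candidates))
    threshold = np.inf
    for i, t in enumerate(candidates):
        n_neg = int(np.sum(w <= -t))
        n_pos = int(np.sum(w >= t))
        fdphat[i] = (config.offset + n_neg) / max(n_pos, 1)
        if fdphat[i] <= config.q and not np.isfinite(threshold):
            threshold = float(t)
    selected = np.flatnonzero(w >= threshold) if np.isfinite(threshold) else np.array([], dtype=int)
    return SelectionResult(
        selected=selected,
        threshold=threshold,
        fdphat_path=fdphat,
        ordering=ascending_magnitude_order(w),
    )


def sequential_filter(W, ordering, config: FilterConfig = FilterConfig()) -> SelectionResult:
    """Sequential (ordered) form of the knockoff filter.

    Given an ordering pi of the p hypotheses, finds the smallest k in
    {0, ..., p-1} with

        (offset + #{j > k: W_pi[j] < 0}) / max(#{j > k: W_pi[j] > 0}, 1) <= q

    and rejects {pi[j] : j > k, W_pi[j] > 0}; the empty set if no k
    qualifies. Counts are accumulated in a single reverse pass.
    """
    w = _as_w(W)
    p = len(w)
    pi = np.asarray(ordering, dtype=int).ravel()
    if sorted(pi.tolist()) != list(range(p)):
        raise ValueError("ordering must be a permutation of 0..p-1")
    w_ord = w[pi]
    # neg_after[k] = #{j > k (1-based), i.e. positions k..p-1 0-based}:
    # reverse cumulative counts of signs among not-yet-dropped hypotheses.
    neg = (w_ord < 0).astype(int)
    pos = (w_ord > 0).astype(int)
    neg_after = np.concatenate([np.cumsum(neg[::-1])[::-1], [0]])
    pos_after = np.concatenate([np.cumsum(pos[::-1])[::-1], [0]])
    ks = np.arange(p)
    fdphat = (config.offset + neg_after[ks]) / np.maximum(pos_after[ks], 1)
    qualifying = np.flatnonzero(fdphat <= config.q)
    if len(qualifying) == 0:
        return SelectionResult(
            selected=np.array([], dtype=int),
            threshold=np.inf,
            fdphat_path=fdphat,
            ordering=pi,
            stop_step=None,
        )
    k = int(qualifying[0])
    keep = pi[k:][w_ord[k:] > 0]
    threshold = float(np.min(np.abs(w[keep]))) if len(keep) else np.inf
    return SelectionResult(
        selected=np.sort(keep),
        threshold=threshold,
        fdphat_path=fdphat[: k + 1],
        ordering=pi,
        stop_step=k,
    )
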
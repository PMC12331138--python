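"""Shared helpers: deterministic seed splitting and column standardization."""

from __future__ import annotations

import numpy as np

# Fixed purpose codes for counter-based seed splitting. Every source of
# randomness in the package derives its generator from
# (master_seed, *context, purpose) through numpy's SeedSequence, so any
# single replicate or environment is reproducible in isolation.
PURPOSE = {
    "support": 0,
    "covariates": 1,
    "noise": 2,
    "knockoffs": 3,
    "cv_folds": 4,
    "column_swap": 5,
    "ordering": 6,
}


def child_seed_sequence(*keys: int) -> np.random.SeedSequence:
    """Derive a child SeedSequence from integer context keys."""
    return np.random.SeedSequence([int(k) for k in keys])


def child_rng(*keys: int) -> np.random.Generator:
    """A Generator deterministically derived from integer context keys."""
    return np.random.default_rng(child_seed_sequence(*keys))


def child_int(*keys: int) -> int:
    """A small integer seed (< 2**31) for APIs that take ints (scikit-learn)."""
    return int(child_seed_sequence(*keys).generate_state(1)[0] % (2**31))


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center columns to zero mean and scale to unit (population) variance.

    Constant columns are centered but left unscaled to avoid division by
    zero; their lasso coefficients are zero regardless.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd
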
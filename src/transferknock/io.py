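"""Delimited-text I/O for designs, statistics and selections.

Conventions: matrices are CSV/TSV with a header row of variable names;
knockoff columns carry a ``.k`` suffix; statistic and weight vectors are
two-column CSV (variable, value); coefficient vectors are CSV whose rows
1..p are originals and p+1..2p the paired knockoffs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gaussian import AugmentedDesign

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_augmented",
    "write_augmented",
    "read_vector",
    "write_vector",
    "read_coefficients",
    "write_coefficients",
    "write_selection",
]

KNOCKOFF_SUFFIX = ".k"


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=_sep(path))
    return df.to_numpy(dtype=float), list(df.columns)


def write_matrix(path, X: np.ndarray, names=None) -> None:
    X = np.asarray(X)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    pd.DataFrame(X, columns=names).to_csv(path, sep=_sep(path), index=False)


def write_augmented(path, design: AugmentedDesign, names=None) -> None:
    p = design.p
    if names is None:
        names = [f"x{j}" for j in range(p)]
    cols = list(names) + [f"{c}{KNOCKOFF_SUFFIX}" for c in names]
    pd.DataFrame(design.XXt, columns=cols).to_csv(path, sep=_sep(path), index=False)


def read_augmented(path) -> tuple[AugmentedDesign, list[str]]:
    X, cols = read_matrix(path)
    p = X.shape[1] // 2
    expected = [f"{c}{KNOCKOFF_SUFFIX}" for c in cols[:p]]
    if X.shape[1] % 2 != 0 or cols[p:] != expected:
        raise ValueError(
            f"{path} is not an augmented design: expected {p} original columns "
            f"followed by their '{KNOCKOFF_SUFFIX}'-suffixed knockoffs"
        )
    return AugmentedDesign(X), cols[:p]


def read_vector(path) -> tuple[np.ndarray, list[str]]:
    """Two-column (variable, value) CSV -> values and names."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(float), [f"x{j}" for j in range(len(df))]
    return df.iloc[:, 1].to_numpy(float), df.iloc[:, 0].astype(str).tolist()


def write_vector(path, values: np.ndarray, names=None, value_col: str = "value") -> None:
    values = np.asarray(values).ravel()
    if names is None:
        names = [f"x{j}" for j in range(len(values))]
    pd.DataFrame({"variable": names, value_col: values}).to_csv(path, sep=_sep(path), index=False)


def write_coefficients(path, coef: np.ndarray, names=None) -> None:
    coef = np.asarray(coef).ravel()
    p = coef.size // 2
    if names is None:
        names = [f"x{j}" for j in range(p)]
    full = list(names) + [f"{c}{KNOCKOFF_SUFFIX}" for c in names]
    pd.DataFrame({"variable": full, "coefficient": coef}).to_csv(path, sep=_sep(path), index=False)


def read_coefficients(path) -> np.ndarray:
    values, _ = read_vector(path)
    if values.size % 2 != 0:
        raise ValueError(f"{path}: coefficient vector length must be even (2p)")
    return values


def write_selection(path, result, names=None) -> None:
    """Selected variables, threshold and stopping step as CSV."""
    sel = np.asarray(result.selected, dtype=int)
    if names is None:
        names = {j: f"x{j}" for j in sel}
        label = [names[j] for j in sel]
    else:
        label = [names[j] for j in sel]
    df = pd.DataFrame(
        {
            "variable": label,
            "index": sel,
            "threshold": result.threshold,
            "stop_step": -1 if result.stop_step is None else result.stop_step,
        }
    )
    df.to_csv(path, sep=_sep(path), index=False)
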
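"""Model/results front end for knockoff-based selection with transfer learning.

:class:`TransferKnockoffs` bundles the full pipeline — Gaussian knockoff
construction, importance statistics, optional transfer of external
information, and the knockoff filter — behind a fit() call that returns a
:class:`TransferKnockoffsResults` with the selected variables, the
statistics, the filter trace and a printable summary, in the spirit of a
statsmodels model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filter import FilterConfig, knockoff_threshold
from .gaussian import (
    AugmentedDesign,
    EnvironmentDataset,
    GaussianDesignModel,
    sample_gaussian_knockoffs,
)
from .statistics import (
    PriorInformation,
    lasso_coefdiff_stats,
    pooled_coefficients,
    prior_weights_from_coefficients,
    weighted_lasso_stats,
)
from .transfer import adaptive_filter, linear_reorder
from .utils import PURPOSE, child_int

__all__ = ["TransferKnockoffs", "TransferKnockoffsResults"]

METHODS = ("vanilla", "weighted_lasso", "linear_reorder", "adaptive")


class TransferKnockoffs:
    """FDR-controlled variable selection in a target environment.

    Parameters
    ----------
    y, X : array-like
        Outcome and n x p design of the target environment.
    externals : sequence of (X_e, y_e) pairs, optional
        External environments whose data inform (but are never tested by)
        the analysis. Required by the transfer methods.
    covariance : (p, p) array, optional
        Known covariate covariance (the model-X assumption). If ``rho`` is
        given instead, an AR(1) correlation matrix is used. If neither is
        supplied, a Ledoit-Wolf shrinkage estimate is substituted; the FDR
        guarantee is then only approximate.
    method : {"vanilla", "linear_reorder", "adaptive", "weighted_lasso"}
    prior : PriorInformation, optional
        Externally supplied prior; by default it is computed from
        ``externals`` at fit time (pooled statistics / coefficients).
    q : float
        Nominal FDR level. ``offset`` 1 gives provable control.
    var_names : sequence of str, optional
    """

    def __init__(self, y, X, externals=None, covariance=None, mean=None, rho=None,
                 method="vanilla", prior=None, q=0.1, offset=1, var_names=None):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        self.target = EnvironmentDataset(X=np.asarray(X, dtype=float),
                                         y=np.asarray(y, dtype=float), env_id=0)
        self.externals = [
            EnvironmentDataset(X=np.asarray(Xe, dtype=float),
                               y=np.asarray(ye, dtype=float), env_id=e + 1)
            for e, (Xe, ye) in enumerate(externals or [])
        ]
        for d in self.externals:
            if d.p != self.target.p:
                raise ValueError("all environments must share the same variables")
        self.method = method
        self.prior = prior
        self.filter_config = FilterConfig(q=q, offset=offset)
        p = self.target.p
        self.var_names = list(var_names) if var_names is not None else [f"x{j}" for j in range(p)]
        if len(self.var_names) != p:
            raise ValueError("var_names length must equal p")
        if covariance is not None:
            self.design_model = GaussianDesignModel.from_covariance(covariance, mean=mean)
        elif rho is not None:
            self.design_model = GaussianDesignModel.from_ar1(p, rho)
        else:
            from sklearn.covariance import LedoitWolf

            Xall = np.vstack([self.target.X] + [d.X for d in self.externals])
            cov = LedoitWolf().fit(Xall).covariance_
            self.design_model = GaussianDesignModel.from_covariance(cov, mean=Xall.mean(axis=0))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, externals=None, **kwargs):
        """Build from a target DataFrame (and optional external DataFrames)
        holding the outcome column named ``outcome``."""
        cols = [c for c in data.columns if c != outcome]
        ext = None
        if externals is not None:
            ext = [(df[cols].to_numpy(float), df[outcome].to_numpy(float)) for df in externals]
        return cls(
            y=data[outcome].to_numpy(float), X=data[cols].to_numpy(float),
            externals=ext, var_names=cols, **kwargs,
        )

    def _augment(self, dataset: EnvironmentDataset, seed: int) -> None:
        aug = sample_gaussian_knockoffs(
            dataset.X, self.design_model,
            child_int(seed, dataset.env_id, PURPOSE["knockoffs"]),
        )
        dataset.knockoffs = aug.knockoffs

    def fit(self, seed: int = 0, theta: float = 0.1, gamma_grid=None,
            cv_folds: int = 10, n_alphas: int = 100, ordering_model="logistic",
            batch: int = 10, phi_source: str = "pooled") -> "TransferKnockoffsResults":
        """Run the pipeline and return the selection results.

        ``theta`` is the mixing weight of the linear re-ordering method
        (must be chosen before looking at the data); ``phi_source``
        chooses whether weighted-lasso prior weights come from the pooled
        data of all environments or only the external ones.
        """
        needs_ext = self.method != "vanilla" and self.prior is None
        if needs_ext and not self.externals:
            raise ValueError(f"method {self.method!r} needs external environments or a prior")
        self._augment(self.target, seed)
        for d in self.externals:
            self._augment(d, seed)

        w0 = lasso_coefdiff_stats(
            self.target.augmented, self.target.y, cv_folds=cv_folds,
            seed=child_int(seed, 10), n_alphas=n_alphas,
        )
        wext = phi = None
        if self.method in ("linear_reorder", "adaptive"):
            if self.prior is not None and self.prior.stat_ext is not None:
                wext = self.prior.stat_ext
            else:
                Z = np.vstack([d.augmented.XXt for d in self.externals])
                yext = np.concatenate([d.y for d in self.externals])
                wext = lasso_coefdiff_stats(
                    AugmentedDesign(Z), yext, cv_folds=cv_folds,
                    seed=child_int(seed, 11), n_alphas=n_alphas,
                ).W

        if self.method == "vanilla":
            W, sel = w0, knockoff_threshold(w0, self.filter_config)
        elif self.method == "linear_reorder":
            W = linear_reorder(w0, wext, theta)
            sel = knockoff_threshold(W, self.filter_config)
        elif self.method == "adaptive":
            priors = self.prior if self.prior is not None else PriorInformation(stat_ext=wext)
            W = w0
            sel = adaptive_filter(
                w0, priors, self.filter_config, model=ordering_model,
                batch=batch, seed=child_int(seed, 12),
            )
        else:  # weighted_lasso
            if self.prior is not None and self.prior.phi is not None:
                phi = self.prior.phi
            else:
                pool = self.externals if phi_source == "external" else [self.target] + self.externals
                coefs = pooled_coefficients(
                    pool, cv_folds=cv_folds, seed=child_int(seed, 13), n_alphas=n_alphas
                )
                phi = prior_weights_from_coefficients(coefs)
            W = weighted_lasso_stats(
                self.target.augmented, self.target.y, phi, gamma_grid=gamma_grid,
                cv_folds=cv_folds, seed=child_int(seed, 10), n_alphas=n_alphas,
            )
            sel = knockoff_threshold(W, self.filter_config)
        return TransferKnockoffsResults(self, W, sel, wext=wext, phi=phi, seed=seed)


class TransferKnockoffsResults:
    """Selection results: statistics, rejection set and filter trace."""

    def __init__(self, model: TransferKnockoffs, statistics, selection,
                 wext=None, phi=None, seed=0):
        self.model = model
        self.statistics = statistics
        self.W_ = np.asarray(statistics.W)
        self.meta_ = dict(statistics.meta)
        self.selection = selection
        self.selected_ = np.asarray(selection.selected, dtype=int)
        self.threshold_ = selection.threshold
        self.fdphat_path_ = selection.fdphat_path
        self.wext_ = None if wext is None else np.asarray(getattr(wext, "W", wext))
        self.phi_ = phi
        self.seed = seed

    @property
    def selected_names_(self) -> list[str]:
        return [self.model.var_names[j] for j in self.selected_]

    @property
    def n_selected(self) -> int:
        return len(self.selected_)

    def to_frame(self) -> pd.DataFrame:
        """Per-variable statistics and selection flags as a DataFrame."""
        df = pd.DataFrame({"variable": self.model.var_names, "W": self.W_})
        if self.wext_ is not None:
            df["W_ext"] = self.wext_
        if self.phi_ is not None:
            df["phi"] = self.phi_
        df["selected"] = np.isin(np.arange(len(self.W_)), self.selected_)
        return df

    def summary(self):
        """Printable summary of the run, statsmodels style."""
        from statsmodels.iolib.table import SimpleTable

        cfg = self.model.filter_config
        info = [
            ("Method:", self.model.method),
            ("No. variables:", str(self.model.target.p)),
            ("No. observations:", str(self.model.target.n)),
            ("External environments:", str(len(self.model.externals))),
            ("Nominal FDR q:", f"{cfg.q:.3g}"),
            ("Filter offset:", str(cfg.offset)),
            ("Threshold:", f"{self.threshold_:.4g}"),
            ("Discoveries:", str(self.n_selected)),
        ]
        header = SimpleTable(
            [[k, v] for k, v in info], headers=["", ""],
            title="Knockoff selection results",
        )
        order = self.selected_[np.argsort(-self.W_[self.selected_])]
        rows = [[self.model.var_names[j], f"{self.W_[j]:.4f}"] for j in order]
        body = SimpleTable(
            rows or [["(none)", ""]], headers=["selected variable", "W"],
        )
        from statsmodels.iolib.summary import Summary

        smry = Summary()
        smry.tables = [header, body]
        return smry

    def plot_statistics(self, ax=None):
        """Stem plot of the statistics with the selection threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        p = len(self.W_)
        ax.vlines(np.arange(p), 0, self.W_, color="lightgray", lw=1)
        ax.scatter(self.selected_, self.W_[self.selected_], color="crimson", s=12,
                   zorder=3, label="selected")
        if np.isfinite(self.threshold_):
            ax.axhline(self.threshold_, ls="--", c="k", lw=1, label="threshold")
        ax.set_xlabel("variable index")
        ax.set_ylabel("W")
        ax.legend(fontsize=8)
        return ax
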
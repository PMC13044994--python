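"""Model / Results interface for the dynamic survival model.

:class:`DynamicSurvivalModel` bundles the data, the event-driven interval
partition and the prior configuration; :meth:`~DynamicSurvivalModel.fit`
runs the MCMC and returns a :class:`DynamicSurvivalResults` carrying the
posterior draws together with summaries, diagnostics, prediction and
plotting.

Example
-------
>>> model = DynamicSurvivalModel.from_dataframe(
...     df, time="time", status="status", covars=["age", "marker"],
...     events_per_interval=2)
>>> res = model.fit(n_iter=5000, burn_in=1000, thin=5, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import (
    IntervalPartition,
    SurvivalDataset,
    build_partition,
    expand,
    read_table,
)
from .prediction import (
    PredictiveSample,
    concordance_index,
    predict_survival_times,
    risk_score,
    survival_curve,
)
from .sampler import PosteriorDraws, SamplerConfig, diagnostics, fit as _fit_mcmc, piecewise_exp_loglik
from .shrinkage import ShrinkageHyperConfig

__all__ = ["DynamicSurvivalModel", "DynamicSurvivalResults"]


class DynamicSurvivalModel:
    """Piecewise-exponential hazard model with shrinkage-selected
    time-varying coefficients and an optional grouped frailty factor.

    Parameters
    ----------
    y, d, Z : array-like
        Observed times, event indicators and covariates (see
        :class:`~shrinksurv.datasets.SurvivalDataset`).
    partition : IntervalPartition, optional
        Fixed partition of the time axis; when omitted it is built by
        placing a grid point after every ``events_per_interval``-th
        observed event.
    groups : array-like, optional
        Group labels enabling the shared-frailty factor block.
    """

    def __init__(
        self,
        y,
        d,
        Z,
        covar_names: list[str] | None = None,
        groups=None,
        z_tv=None,
        partition: IntervalPartition | None = None,
        events_per_interval: int = 2,
    ):
        self.dataset = SurvivalDataset(
            y=y, d=d, Z=Z, z_tv=z_tv, group=groups, covar_names=covar_names
        )
        if partition is None:
            events = self.dataset.y[self.dataset.d == 1]
            partition = build_partition(
                events, events_per_interval, max_time=float(self.dataset.y.max())
            )
        self.partition = partition
        self.expanded = expand(self.dataset, partition)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        status: str = "status",
        covars: list[str] | None = None,
        groups: str | None = None,
        **kwargs,
    ) -> "DynamicSurvivalModel":
        if covars is None:
            covars = [c for c in df.columns if c not in {time, status, groups}]
        return cls(
            y=df[time].to_numpy(dtype=float),
            d=df[status].to_numpy(),
            Z=df[covars].to_numpy(dtype=float) if covars else np.empty((len(df), 0)),
            covar_names=list(covars),
            groups=df[groups].to_numpy() if groups else None,
            **kwargs,
        )

    @classmethod
    def from_csv(cls, path, time="time", status="status", covars=None, groups=None, **kwargs):
        ds = read_table(path, time=time, status=status, covars=covars, group=groups)
        return cls(
            y=ds.y, d=ds.d, Z=ds.Z, covar_names=ds.covar_names, groups=ds.group, **kwargs
        )

    def fit(
        self,
        n_iter: int = 50_000,
        burn_in: int = 10_000,
        thin: int = 10,
        seed: int = 0,
        factor: bool | None = None,
        config: SamplerConfig | None = None,
        **config_kwargs,
    ) -> "DynamicSurvivalResults":
        """Run the MCMC sampler and wrap the draws in a results object.

        ``factor`` defaults to True exactly when group labels are present.
        Additional :class:`~shrinksurv.sampler.SamplerConfig` fields
        (``shrinkage``, ``sv``, ``time_varying``, ...) may be passed as
        keyword arguments, or a fully built ``config`` supplied.
        """
        if config is None:
            if factor is None:
                factor = self.dataset.group is not None
            config = SamplerConfig(
                n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, factor=factor,
                **config_kwargs,
            )
        draws = _fit_mcmc(self.dataset, self.partition, config)
        return DynamicSurvivalResults(self, draws)


class DynamicSurvivalResults:
    """Posterior draws of a fitted dynamic survival model, with summaries."""

    def __init__(self, model: DynamicSurvivalModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # --- summaries -------------------------------------------------------
    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Posterior summary per coefficient.

        ``beta_mean`` columns summarise the initial-mean parameters (the
        static effect when ``theta`` is shrunk to zero); ``theta_median``
        is the posterior median innovation variance — values near zero
        indicate an effectively constant effect, and together with a
        near-zero mean an excluded covariate.
        """
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        names = ["baseline"] + list(self.draws.covar_names)
        bm, th = self.draws.beta_mean, self.draws.theta
        return pd.DataFrame(
            {
                "median": np.median(bm, axis=0),
                f"{100 * lo:g}%": np.quantile(bm, lo, axis=0),
                f"{100 * hi:g}%": np.quantile(bm, hi, axis=0),
                "theta_median": np.median(th, axis=0),
                "P(theta>0.01)": np.mean(th > 0.01, axis=0),
            },
            index=pd.Index(names, name="coefficient"),
        )

    def coefficient_paths(self, q=(0.025, 0.5, 0.975)) -> dict:
        """Pointwise posterior quantiles of each coefficient path.

        Returns a dict with the grid midpoints and an array of shape
        ``(len(q), J, K+1)``.
        """
        S = self.draws.partition.S
        mid = 0.5 * (S[:-1] + S[1:])
        quant = np.quantile(self.draws.beta[:, 1:, :], q, axis=0)
        return {"time": mid, "quantiles": quant, "q": tuple(q)}

    def diagnostics(self) -> pd.DataFrame:
        return diagnostics(self.draws)

    def loglik_draws(self) -> np.ndarray:
        """Exact piecewise-exponential log-likelihood per stored draw."""
        hz = self.draws.hazards(self.model.dataset, self.model.expanded)
        return piecewise_exp_loglik(self.model.expanded, hz)

    # --- prediction ------------------------------------------------------
    def predict_survival_times(
        self, z_new, n_pred: int = 10_000, rng=None, **kwargs
    ) -> PredictiveSample:
        return predict_survival_times(self.draws, z_new, n_pred=n_pred, rng=rng, **kwargs)

    def risk_score(self, z_new, n_pred: int = 10_000, rng=None, **kwargs) -> float:
        return risk_score(self.draws, z_new, n_pred=n_pred, rng=rng, **kwargs)

    def survival_curve(self, z_new, grid, group: int | None = None) -> np.ndarray:
        return survival_curve(self.draws, z_new, grid, group=group)

    def concordance(self, times, events, scores) -> float:
        return concordance_index(times, events, scores)

    # --- plotting --------------------------------------------------------
    def plot_coefficients(self, covars=None, ax=None):
        """Posterior median paths with 50% and 95% pointwise bands."""
        import matplotlib.pyplot as plt

        paths = self.coefficient_paths(q=(0.025, 0.25, 0.5, 0.75, 0.975))
        names = ["baseline"] + list(self.draws.covar_names)
        if covars is None:
            covars = names
        idx = [names.index(c) for c in covars]
        n = len(idx)
        if ax is None:
            fig, axes = plt.subplots(n, 1, figsize=(7, 2.2 * n), sharex=True, squeeze=False)
            axes = axes.ravel()
        else:
            axes = np.atleast_1d(ax)
        t = paths["time"]
        qs = paths["quantiles"]
        for a, k in zip(axes, idx):
            a.fill_between(t, qs[0, :, k], qs[4, :, k], alpha=0.2, label="95%")
            a.fill_between(t, qs[1, :, k], qs[3, :, k], alpha=0.35, label="50%")
            a.plot(t, qs[2, :, k], color="k", lw=1.2)
            a.axhline(0.0, color="grey", lw=0.6, ls=":")
            a.set_ylabel(names[k])
        axes[-1].set_xlabel("time")
        return axes

    def save(self, path) -> None:
        self.draws.save(path)

    def __repr__(self) -> str:
        return (
            f"<DynamicSurvivalResults: {self.draws.n_draws} draws, "
            f"J={self.draws.partition.J} intervals, "
            f"{len(self.draws.covar_names)} covariates"
            f"{', factor' if self.draws.has_factor else ''}>"
        )
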
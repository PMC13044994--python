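"""MCMC orchestration for the dynamic survival model.

One sweep of the Gibbs sampler, in fixed, documented order:

1. residual survival times ``tau_ij`` given current hazards;
2. Gumbel-mixture component indicators and pseudo-observations;
3. FFBS draw of the coefficient paths ``beta_{0:J}`` (factor offset
   residualised out when the factor block is enabled);
4. initial means ``beta_k`` (conjugate, centered parameterisation);
5. innovation variances ``theta_k``: centered GIG draw, then an
   interweaving joint non-centered draw of ``(beta_k, ±sqrt(theta_k))``;
6. local/global triple-gamma scales of both layers;
7. MH-within-Gibbs for the pole/tail parameters a, c;
8. factor block (factor path, loadings, loading shrinkage, SV) if enabled.

Proposal scales adapt toward ~35% acceptance during burn-in only, so the
post-burn-in chain is a fixed Markov kernel.  The chain state lives in
:class:`_GibbsChain`, which also supports swapping the dataset between
sweeps (used by simulation-based validity checks).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .augmentation import build_pseudo_observations, draw_mixture_indicators, draw_residual_times
from .datasets import ExpandedData, IntervalPartition, SurvivalDataset, design_rows, expand
from .factor_sv import FactorState, SVHyperConfig, sample_factor, sample_loadings, sample_sv_block
from .gumbel import build_gumbel_mixture, build_log_chi2_mixture
from .shrinkage import (
    ShrinkageHyperConfig,
    TripleGammaLayer,
    sample_conjugate_regression,
    sample_initial_means,
    sample_means_scales_ncp,
    sample_pole_tail_mh,
    sample_theta_centered,
    update_triple_gamma_layer,
)
from .state_space import GaussianStateSpace, ffbs

__all__ = ["SamplerConfig", "PosteriorDraws", "fit", "piecewise_exp_loglik", "diagnostics"]

logger = logging.getLogger("shrinksurv")

_LINPRED_CLIP = 500.0  # guards exp() overflow in early, unconverged sweeps


@dataclass
class SamplerConfig:
    """Run-length, prior and feature configuration of the sampler.

    The default run length (50,000 sweeps, 10,000 burn-in, thinning 10,
    hence 4,000 stored draws) matches the simulation-study setting.
    ``time_varying=False`` fixes every ``theta_k`` at the variance floor,
    giving the internal constant-coefficient baseline model.
    """

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    shrinkage: ShrinkageHyperConfig = field(default_factory=ShrinkageHyperConfig)
    phi_shrinkage: ShrinkageHyperConfig = field(default_factory=ShrinkageHyperConfig)
    sv: SVHyperConfig = field(default_factory=SVHyperConfig)
    factor: bool = False
    time_varying: bool = True
    variance_floor: float = 1e-12
    allow_individual_frailty: bool = False
    store_hazards: bool = False
    progress: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of every model block.

    ``beta`` holds the state paths (draw, interval 0..J, coefficient) with
    coefficient 0 the baseline log-hazard.  Derived hazards
    ``lambda_ij = exp(phi_g f_j + z_i beta_j)`` are exposed through
    :meth:`hazards` (and stored only on request — they are the largest
    object in the model by far).
    """

    beta: np.ndarray  # (D, J+1, m)
    beta_mean: np.ndarray  # (D, m)
    theta: np.ndarray  # (D, m)
    lam_beta: np.ndarray
    tau_beta: np.ndarray
    lam_theta: np.ndarray
    tau_theta: np.ndarray
    a_beta: np.ndarray
    c_beta: np.ndarray
    a_theta: np.ndarray
    c_theta: np.ndarray
    partition: IntervalPartition
    covar_names: list[str]
    seed: int
    config: dict = field(default_factory=dict)
    phi: np.ndarray | None = None  # (D, G)
    f: np.ndarray | None = None  # (D, J)
    h: np.ndarray | None = None  # (D, J+1)
    phi_sv: np.ndarray | None = None
    sigma2_f: np.ndarray | None = None
    lam_phi: np.ndarray | None = None
    tau_phi: np.ndarray | None = None
    a_phi: np.ndarray | None = None
    c_phi: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)
    hazard_draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def has_factor(self) -> bool:
        return self.phi is not None

    def linear_predictor(self, dataset: SurvivalDataset, expanded: ExpandedData) -> np.ndarray:
        """Per-draw log-hazards over the flat (subject, interval) pairs."""
        Z = design_rows(dataset, expanded)
        lp = np.einsum("pm,dpm->dp", Z, self.beta[:, expanded.interval, :])
        if self.has_factor and dataset.group is not None:
            lp += self.phi[:, dataset.group[expanded.subject]] * self.f[:, expanded.interval - 1]
        return lp

    def hazards(self, dataset: SurvivalDataset, expanded: ExpandedData) -> np.ndarray:
        """Derived piecewise-constant hazards ``lambda_ij`` per stored draw."""
        return np.exp(np.clip(self.linear_predictor(dataset, expanded), -_LINPRED_CLIP, _LINPRED_CLIP))

    def save(self, path) -> None:
        """Persist draws as a columnar .npz with a JSON metadata sidecar."""
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {k: v for k, v in vars(self).items() if isinstance(v, np.ndarray)}
        arrays["partition_S"] = self.partition.S
        np.savez(path / "draws.npz", **arrays)
        meta = {
            "seed": self.seed,
            "config": self.config,
            "covar_names": self.covar_names,
            "acceptance": self.acceptance,
            "n_draws": self.n_draws,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        from pathlib import Path

        path = Path(path)
        with np.load(path / "draws.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads((path / "meta.json").read_text())
        S = arrays.pop("partition_S")
        return cls(
            partition=IntervalPartition(S),
            covar_names=meta["covar_names"],
            seed=meta["seed"],
            config=meta["config"],
            acceptance=meta["acceptance"],
            **arrays,
        )


def piecewise_exp_loglik(expanded: ExpandedData, hazards: np.ndarray) -> float:
    """Exact piecewise-exponential log-likelihood
    ``sum_ij [ event_ij ln(lambda_ij) - lambda_ij u_ij ]``."""
    hazards = np.asarray(hazards, dtype=float)
    if hazards.shape[-1] != expanded.u.shape[0]:
        raise ValueError("hazards do not align with the expanded exposures")
    ll = np.sum(np.log(hazards[..., expanded.event]), axis=-1) - hazards @ expanded.u
    return float(ll) if np.ndim(ll) == 0 else ll


class _GibbsChain:
    """Mutable state of the Gibbs sampler plus one-`sweep` transition."""

    def __init__(
        self,
        dataset: SurvivalDataset,
        partition: IntervalPartition,
        config: SamplerConfig,
        rng: np.random.Generator,
        expanded: ExpandedData | None = None,
    ):
        self.partition = partition
        self.config = config
        self.rng = rng
        self.J = partition.J
        self.m = dataset.n_covariates + 1
        self.mixture = build_gumbel_mixture()
        hyp = config.shrinkage

        self.use_factor = config.factor
        if self.use_factor:
            if dataset.group is None:
                raise ValueError("factor=True requires group labels in the dataset")
            self.G = dataset.n_groups
            if self.G >= dataset.n_subjects and not config.allow_individual_frailty:
                raise ValueError(
                    "individual-level frailty (G = N) is weakly identified with "
                    "time-varying effects; set allow_individual_frailty=True to override"
                )
            self.sv_mixture = build_log_chi2_mixture()
            self.fstate = FactorState.initial(
                self.G, self.J,
                a=config.phi_shrinkage.fixed_a_beta, c=config.phi_shrinkage.fixed_c_beta,
            )
            self.log_sd_sv = np.log(0.5)

        self.beta_path = np.zeros((self.J + 1, self.m))
        self.beta_mean = np.zeros(self.m)
        self.level_log_sd = np.full(self.m, np.log(0.2))
        self.level_accept = np.zeros(self.m, dtype=int)
        self.level_tries = np.zeros(self.m, dtype=int)
        self.theta = np.full(self.m, 0.01 if config.time_varying else config.variance_floor)
        self.lay_t = TripleGammaLayer.initial(self.m, a=hyp.fixed_a_theta, c=hyp.fixed_c_theta)
        self.lay_b = TripleGammaLayer.initial(self.m, a=hyp.fixed_a_beta, c=hyp.fixed_c_beta)
        self.set_data(dataset, expanded)

    def set_data(self, dataset: SurvivalDataset, expanded: ExpandedData | None = None) -> None:
        """Attach (or replace) the dataset; the partition stays fixed."""
        self.dataset = dataset
        self.expanded = expanded if expanded is not None else expand(dataset, self.partition)
        self.Zfull = design_rows(dataset, self.expanded)
        self.pair_interval = self.expanded.interval
        self.slices = [self.expanded.pairs_of_interval(j) for j in range(1, self.J + 1)]
        self.Zviews = [self.Zfull[s] for s in self.slices]
        if self.use_factor:
            self.pair_group = dataset.group[self.expanded.subject]

    def sweep(self, adapting: bool = False) -> None:
        cfg, rng, m, J = self.config, self.rng, self.m, self.J
        hyp = cfg.shrinkage
        expanded, Zfull, pair_interval = self.expanded, self.Zfull, self.pair_interval

        # (0) exact-likelihood level move.  The augmented pseudo-data carry
        # far more nominal information than the observed events (every
        # censored pair acts as a complete exponential observation), so the
        # conditionally Gaussian blocks move each coefficient's *global
        # level* in very small steps.  A Metropolis shift of the whole path
        # (and its initial mean) against the exact piecewise-exponential
        # likelihood fixes that slow mode.  Placed immediately before the
        # augmentation redraw, the move targets the marginal posterior and
        # the subsequent exact conditional draw of (tau, r) restores the
        # joint — a standard collapsed-move composition.
        self._level_move(adapting)

        # (1)-(2) data augmentation
        lp_beta = np.einsum("pm,pm->p", Zfull, self.beta_path[pair_interval])
        linpred = lp_beta
        if self.use_factor:
            factor_offset = self.fstate.phi[self.pair_group] * self.fstate.f[pair_interval - 1]
            linpred = lp_beta + factor_offset
        hazards = np.exp(np.clip(linpred, -_LINPRED_CLIP, _LINPRED_CLIP))
        tau = draw_residual_times(expanded, hazards, rng)
        r = draw_mixture_indicators(tau, linpred, self.mixture, rng)
        x, v = build_pseudo_observations(tau, r, self.mixture)
        x_beta = x - factor_offset if self.use_factor else x

        if cfg.time_varying:
            # (3) FFBS for the coefficient paths
            model = GaussianStateSpace(
                x=[x_beta[s] for s in self.slices],
                Zmat=self.Zviews,
                V=[v[s] for s in self.slices],
                Q=self.theta,
                a0=self.beta_mean,
                P0=np.maximum(self.theta, cfg.variance_floor),
                variance_floor=cfg.variance_floor,
            )
            self.beta_path = ffbs(model, rng)

            # (4) initial means (centered)
            theta_eff = np.maximum(self.theta, cfg.variance_floor)
            self.beta_mean = sample_initial_means(
                self.beta_path[0], theta_eff, self.lay_b.lam, self.lay_b.tau, rng
            )

            # (5) theta: centered GIG draw, then interweaved non-centered joint draw
            theta = sample_theta_centered(
                self.beta_path, self.beta_mean, self.lay_t.lam, self.lay_t.tau, rng
            )
            theta = np.maximum(theta, cfg.variance_floor)
            signs = rng.choice([-1.0, 1.0], size=m)
            sqrt_theta = signs * np.sqrt(theta)
            btilde = (self.beta_path - self.beta_mean) / sqrt_theta
            self.beta_mean, sqrt_theta = sample_means_scales_ncp(
                x_beta, v, Zfull, btilde[pair_interval],
                self.lay_b.prior_var, self.lay_t.prior_var, rng,
            )
            self.theta = np.maximum(sqrt_theta**2, cfg.variance_floor)
            self.beta_path = self.beta_mean + sqrt_theta * btilde
        else:
            # constant-coefficient baseline: theta pinned to the floor means
            # the path equals its initial mean, whose exact conditional is a
            # single conjugate Gaussian regression on the pseudo-observations
            self.beta_mean = sample_conjugate_regression(
                x_beta, v, Zfull, self.lay_b.prior_var, rng
            )
            self.beta_path = np.tile(self.beta_mean, (J + 1, 1))

        # (6) shrinkage scales
        update_triple_gamma_layer(self.beta_mean**2, self.lay_b, rng)
        if cfg.time_varying:
            update_triple_gamma_layer(self.theta, self.lay_t, rng)

        # (7) MH for pole/tail parameters
        specs = (
            (self.lay_b, hyp.learn_a_beta, hyp.learn_c_beta,
             hyp.alpha_a_beta, hyp.beta_a_beta, hyp.alpha_c_beta, hyp.beta_c_beta),
            (self.lay_t, hyp.learn_a_theta and cfg.time_varying,
             hyp.learn_c_theta and cfg.time_varying,
             hyp.alpha_a_theta, hyp.beta_a_theta, hyp.alpha_c_theta, hyp.beta_c_theta),
        )
        for lay, learn_a, learn_c, al_a, be_a, al_c, be_c in specs:
            self._mh_pole_tail(lay, learn_a, learn_c, al_a, be_a, al_c, be_c, adapting)

        # (8) factor block
        if self.use_factor:
            fstate = self.fstate
            lp_beta = np.einsum("pm,pm->p", Zfull, self.beta_path[pair_interval])
            x_f = x - lp_beta
            fstate.f = sample_factor(
                x_f, v, self.pair_group, pair_interval, J, fstate.phi, fstate.h, rng
            )
            fstate.phi = sample_loadings(
                x_f, v, self.pair_group, pair_interval, self.G, fstate.f,
                fstate.layer.prior_var, rng,
            )
            update_triple_gamma_layer(fstate.phi**2, fstate.layer, rng)
            ph = cfg.phi_shrinkage
            self._mh_pole_tail(
                fstate.layer, ph.learn_a_beta, ph.learn_c_beta,
                ph.alpha_a_beta, ph.beta_a_beta, ph.alpha_c_beta, ph.beta_c_beta, adapting,
            )
            fstate.h, fstate.phi_sv, fstate.sigma2_f, self.log_sd_sv = sample_sv_block(
                fstate.f, fstate, cfg.sv, rng, mixture=self.sv_mixture,
                adapt=adapting, log_sd=self.log_sd_sv,
            )

        if not np.all(np.isfinite(self.beta_path)):
            raise FloatingPointError("non-finite coefficient state (FFBS block)")

    def _level_move(self, adapting: bool) -> None:
        rng = self.rng
        lp = np.einsum("pm,pm->p", self.Zfull, self.beta_path[self.pair_interval])
        if self.use_factor:
            lp = lp + self.fstate.phi[self.pair_group] * self.fstate.f[self.pair_interval - 1]
        lam_u = np.exp(np.clip(lp, -_LINPRED_CLIP, _LINPRED_CLIP)) * self.expanded.u
        ev = self.expanded.event
        prior_var = self.lay_b.prior_var
        for k in range(self.m):
            z_k = self.Zfull[:, k]
            delta = np.exp(self.level_log_sd[k]) * rng.standard_normal()
            d_loglik = delta * float(z_k[ev].sum()) - float(
                lam_u @ np.expm1(np.clip(delta * z_k, -_LINPRED_CLIP, _LINPRED_CLIP))
            )
            new_mean = self.beta_mean[k] + delta
            d_logprior = -(new_mean**2 - self.beta_mean[k] ** 2) / (2.0 * prior_var[k])
            accept = np.log(rng.random()) < d_loglik + d_logprior
            if accept:
                self.beta_path[:, k] += delta
                self.beta_mean = self.beta_mean.copy()
                self.beta_mean[k] = new_mean
                shift = delta * z_k
                lam_u = lam_u * np.exp(np.clip(shift, -_LINPRED_CLIP, _LINPRED_CLIP))
            if adapting:
                self.level_log_sd[k] += 0.05 * ((1.0 if accept else 0.0) - 0.35)
            self.level_accept[k] += int(accept)
            self.level_tries[k] += 1

    def _mh_pole_tail(self, lay, learn_a, learn_c, al_a, be_a, al_c, be_c, adapting):
        rng = self.rng
        lay.tries += 1
        if learn_a:
            gammas = np.concatenate([lay.psi, [lay.zeta_tau]])
            lay.a, acc, lay.log_sd_a = sample_pole_tail_mh(
                lay.a, gammas, al_a, be_a, lay.log_sd_a, rng, adapt=adapting
            )
            lay.accept_a += int(acc)
        if learn_c:
            gammas = np.concatenate([lay.zeta, [lay.psi_tau]])
            lay.c, acc, lay.log_sd_c = sample_pole_tail_mh(
                lay.c, gammas, al_c, be_c, lay.log_sd_c, rng, adapt=adapting
            )
            lay.accept_c += int(acc)

    def current_hazard_pairs(self) -> np.ndarray:
        lp = np.einsum("pm,pm->p", self.Zfull, self.beta_path[self.pair_interval])
        if self.use_factor:
            lp = lp + self.fstate.phi[self.pair_group] * self.fstate.f[self.pair_interval - 1]
        return np.exp(np.clip(lp, -_LINPRED_CLIP, _LINPRED_CLIP))


def fit(
    dataset: SurvivalDataset,
    partition: IntervalPartition,
    config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Run the full data-augmentation Gibbs sampler.

    Fully reproducible: the same seed, data and configuration give bitwise
    identical draws.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    chain = _GibbsChain(dataset, partition, config, rng)
    J, m = chain.J, chain.m

    D = config.n_draws
    store = {
        "beta": np.empty((D, J + 1, m)),
        "beta_mean": np.empty((D, m)),
        "theta": np.empty((D, m)),
        "lam_beta": np.empty((D, m)),
        "tau_beta": np.empty(D),
        "lam_theta": np.empty((D, m)),
        "tau_theta": np.empty(D),
        "a_beta": np.empty(D),
        "c_beta": np.empty(D),
        "a_theta": np.empty(D),
        "c_theta": np.empty(D),
    }
    if chain.use_factor:
        store.update(
            phi=np.empty((D, chain.G)),
            f=np.empty((D, J)),
            h=np.empty((D, J + 1)),
            phi_sv=np.empty(D),
            sigma2_f=np.empty(D),
            lam_phi=np.empty((D, chain.G)),
            tau_phi=np.empty(D),
            a_phi=np.empty(D),
            c_phi=np.empty(D),
        )
    if config.store_hazards:
        store["hazard_draws"] = np.empty((D, chain.expanded.n_pairs))

    t_start = time.time()
    milestone = max(config.n_iter // 10, 1)
    d_ix = 0
    for it in range(1, config.n_iter + 1):
        try:
            chain.sweep(adapting=it <= config.burn_in)
        except FloatingPointError as err:
            raise FloatingPointError(f"sweep {it}: {err}") from err

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            store["beta"][d_ix] = chain.beta_path
            store["beta_mean"][d_ix] = chain.beta_mean
            store["theta"][d_ix] = chain.theta
            store["lam_beta"][d_ix] = chain.lay_b.lam
            store["tau_beta"][d_ix] = chain.lay_b.tau
            store["lam_theta"][d_ix] = chain.lay_t.lam
            store["tau_theta"][d_ix] = chain.lay_t.tau
            store["a_beta"][d_ix] = chain.lay_b.a
            store["c_beta"][d_ix] = chain.lay_b.c
            store["a_theta"][d_ix] = chain.lay_t.a
            store["c_theta"][d_ix] = chain.lay_t.c
            if chain.use_factor:
                fstate = chain.fstate
                store["phi"][d_ix] = fstate.phi
                store["f"][d_ix] = fstate.f
                store["h"][d_ix] = fstate.h
                store["phi_sv"][d_ix] = fstate.phi_sv
                store["sigma2_f"][d_ix] = fstate.sigma2_f
                store["lam_phi"][d_ix] = fstate.layer.lam
                store["tau_phi"][d_ix] = fstate.layer.tau
                store["a_phi"][d_ix] = fstate.layer.a
                store["c_phi"][d_ix] = fstate.layer.c
            if config.store_hazards:
                store["hazard_draws"][d_ix] = chain.current_hazard_pairs()
            d_ix += 1

        if it % milestone == 0:
            msg = (
                f"sweep {it}/{config.n_iter} ({100 * it // config.n_iter}%), "
                f"{time.time() - t_start:.1f}s elapsed; "
                f"MH acceptance a_beta {chain.lay_b.accept_a / chain.lay_b.tries:.2f}, "
                f"a_theta {chain.lay_t.accept_a / chain.lay_t.tries:.2f}"
            )
            logger.info(msg)
            if config.progress:
                print(msg)

    acceptance = {
        "a_beta": chain.lay_b.accept_a / max(chain.lay_b.tries, 1),
        "c_beta": chain.lay_b.accept_c / max(chain.lay_b.tries, 1),
        "a_theta": chain.lay_t.accept_a / max(chain.lay_t.tries, 1),
        "c_theta": chain.lay_t.accept_c / max(chain.lay_t.tries, 1),
    }
    if chain.use_factor:
        fstate = chain.fstate
        acceptance["a_phi"] = fstate.layer.accept_a / max(fstate.layer.tries, 1)
        acceptance["c_phi"] = fstate.layer.accept_c / max(fstate.layer.tries, 1)
        acceptance["phi_sv"] = fstate.accept_phi_sv / max(fstate.tries_phi_sv, 1)

    return PosteriorDraws(
        partition=partition,
        covar_names=list(dataset.covar_names),
        seed=config.seed,
        config=asdict(config),
        acceptance=acceptance,
        **store,
    )


def fit_chains(
    dataset: SurvivalDataset,
    partition: IntervalPartition,
    config: SamplerConfig | None = None,
    n_chains: int = 2,
) -> list[PosteriorDraws]:
    """Convenience wrapper: run ``n_chains`` independent chains serially.

    Chain ``i`` uses seed ``config.seed + i``; use the resulting list with
    :func:`diagnostics` (stack matching scalars as (chain, draw) arrays)
    for proper multi-chain R-hat.
    """
    from dataclasses import replace

    config = config or SamplerConfig()
    return [fit(dataset, partition, replace(config, seed=config.seed + i)) for i in range(n_chains)]


def diagnostics(draws: PosteriorDraws | dict, min_draws: int = 100) -> pd.DataFrame:
    """Per-scalar effective sample sizes and split-R-hat.

    Accepts a :class:`PosteriorDraws` (summarising means, variances, shrinkage
    globals and pole/tail parameters) or a plain dict of 1-D chains.  Flags
    any split-R-hat above 1.1.  The single stored chain is split in half to
    form the two split chains.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        chains: dict[str, np.ndarray] = {}
        names = ["baseline"] + list(draws.covar_names)
        for k, name in enumerate(names):
            chains[f"beta_mean[{name}]"] = draws.beta_mean[:, k]
            chains[f"theta[{name}]"] = draws.theta[:, k]
        for scalar in ("tau_beta", "tau_theta", "a_beta", "c_beta", "a_theta", "c_theta"):
            chains[scalar] = getattr(draws, scalar)
        if draws.has_factor:
            chains["phi_sv"] = draws.phi_sv
            chains["sigma2_f"] = draws.sigma2_f
    else:
        chains = {k: np.asarray(val) for k, val in draws.items()}
    rows = []
    for name, chain in chains.items():
        chain = np.asarray(chain, dtype=float)
        if chain.ndim == 1:
            if chain.shape[0] < min_draws:
                raise ValueError(f"need at least {min_draws} draws for diagnostics ({name})")
            half = chain.shape[0] // 2
            split = np.stack([chain[:half], chain[half : 2 * half]])
        else:
            if chain.shape[0] < 2 or chain.shape[1] < 2:
                raise ValueError("multi-chain input needs >= 2 chains with >= 2 draws")
            split = chain
        if np.allclose(split.std(), 0.0):
            ess, rhat = 0.0, np.inf  # a stuck chain
        else:
            ds = az.convert_to_dataset(split)
            ess = float(np.asarray(az.ess(ds)["x"]))
            rhat = float(np.asarray(az.rhat(ds)["x"]))
        rows.append({"parameter": name, "ess": ess, "rhat": rhat, "flagged": rhat > 1.1})
    return pd.DataFrame(rows).set_index("parameter")
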
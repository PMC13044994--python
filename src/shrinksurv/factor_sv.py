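"""Grouped latent-factor frailty with stochastic volatility.

When subjects carry observed group labels ``g in {1..G}`` the log-hazard
gains a shared term ``phi_g f_j``: a single latent factor ``f_j`` per
interval, scaled by one loading per group.  The factor follows a zero-mean
stochastic-volatility law of motion,

    f_j | h_j ~ N(0, exp(h_j)),
    h_j = phi_sv h_{j-1} + eta_j,   eta_j ~ N(0, sigma_f^2),
    h_0 ~ N(0, sigma_f^2 / (1 - phi_sv^2)),

so the magnitude of the shared frailty may itself drift over time.  The
loadings carry the same triple-gamma shrinkage as the coefficient layer, so
uninformative groups are shrunk out.  Signs of (phi, f) are not separately
identified — ``phi f = (-phi)(-f)`` — and are fixed post-hoc by flipping
whole draws so that ``phi_1 >= 0``.

This shared-frailty regime assumes G < N; G = N (individual frailty) is
weakly identified alongside time-varying effects and requires an explicit
override in the sampler configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gumbel import NormalMixture, build_log_chi2_mixture
from .shrinkage import TripleGammaLayer, sample_gig

__all__ = [
    "SVHyperConfig",
    "FactorState",
    "sample_factor",
    "sample_loadings",
    "sample_sv_block",
    "identify_signs",
]

_LNF2_OFFSET = 1e-8  # guards ln f_j^2 at f_j ~ 0 in the SV auxiliary step


@dataclass
class SVHyperConfig:
    """Priors for the SV law of motion: ``(phi_sv+1)/2 ~ Beta(a_sv, b_sv)``,
    ``sigma_f^2 ~ Gamma(1/2, rate 1/(2 B_sv))``."""

    a_sv: float = 5.0
    b_sv: float = 1.5
    B_sv: float = 1.0


@dataclass
class FactorState:
    phi: np.ndarray  # (G,) loadings
    f: np.ndarray  # (J,) factor values, intervals 1..J
    h: np.ndarray  # (J+1,) log-variances, index 0 = pre-sample
    phi_sv: float
    sigma2_f: float
    layer: TripleGammaLayer = None  # shrinkage hierarchy of the loadings
    accept_phi_sv: int = 0
    tries_phi_sv: int = 0

    @classmethod
    def initial(cls, G: int, J: int, a: float = 0.1, c: float = 0.1) -> "FactorState":
        return cls(
            phi=np.zeros(G),
            f=np.zeros(J),
            h=np.zeros(J + 1),
            phi_sv=0.5,
            sigma2_f=0.1,
            layer=TripleGammaLayer.initial(G, a=a, c=c),
        )


def sample_factor(
    x_resid: np.ndarray,
    v: np.ndarray,
    pair_group: np.ndarray,
    pair_interval: np.ndarray,
    J: int,
    phi: np.ndarray,
    h: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw of the factor path, independently per interval.

    ``x_resid`` are the pseudo-observations residualised on ``z_i beta_j``;
    the interval-``j`` conditional is normal with precision
    ``exp(-h_j) + sum phi_g^2 / v`` over the risk set.
    """
    if pair_group is None:
        raise ValueError("the factor block requires group labels")
    w = phi[pair_group]
    prec = np.bincount(pair_interval - 1, weights=w**2 / v, minlength=J) + np.exp(-h[1:])
    rhs = np.bincount(pair_interval - 1, weights=w * x_resid / v, minlength=J)
    mean = rhs / prec
    return rng.normal(mean, np.sqrt(1.0 / prec))


def sample_loadings(
    x_resid: np.ndarray,
    v: np.ndarray,
    pair_group: np.ndarray,
    pair_interval: np.ndarray,
    G: int,
    f: np.ndarray,
    prior_var: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw of the loadings under their normal scale-mixture prior."""
    fpair = f[pair_interval - 1]
    prec = np.bincount(pair_group, weights=fpair**2 / v, minlength=G) + 1.0 / prior_var
    rhs = np.bincount(pair_group, weights=fpair * x_resid / v, minlength=G)
    counts = np.bincount(pair_group, minlength=G)
    if np.any(counts == 0):
        warnings.warn("empty group: loading sampled from its prior", stacklevel=2)
    return rng.normal(rhs / prec, np.sqrt(1.0 / prec))


def _ar1_ffbs(
    ystar: np.ndarray,
    obs_mean: np.ndarray,
    obs_var: np.ndarray,
    phi_sv: float,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scalar AR(1) forward-filter backward-sampler for the log-variance path."""
    J = ystar.shape[0]
    a = np.empty(J + 1)
    P = np.empty(J + 1)
    a[0] = 0.0
    P[0] = sigma2 / (1.0 - phi_sv**2)
    for j in range(1, J + 1):
        ap = phi_sv * a[j - 1]
        Pp = phi_sv**2 * P[j - 1] + sigma2
        K = Pp / (Pp + obs_var[j - 1])
        a[j] = ap + K * (ystar[j - 1] - obs_mean[j - 1] - ap)
        P[j] = (1.0 - K) * Pp
    h = np.empty(J + 1)
    h[J] = rng.normal(a[J], np.sqrt(P[J]))
    for j in range(J - 1, -1, -1):
        Pp = phi_sv**2 * P[j] + sigma2
        G = phi_sv * P[j] / Pp
        mean = a[j] + G * (h[j + 1] - phi_sv * a[j])
        var = P[j] - G * phi_sv * P[j]
        h[j] = rng.normal(mean, np.sqrt(max(var, 0.0)))
    return h


def sample_sv_block(
    f: np.ndarray,
    state: FactorState,
    hyper: SVHyperConfig,
    rng: np.random.Generator,
    mixture: NormalMixture | None = None,
    adapt: bool = False,
    log_sd: float = np.log(0.5),
) -> tuple[np.ndarray, float, float, float]:
    """Update (h, phi_sv, sigma_f^2) given the factor path.

    ``ln(f_j^2 + offset) = h_j + ln chi^2_1`` noise is linearised with the
    10-component auxiliary mixture; ``h`` is then drawn by an AR(1) FFBS,
    ``phi_sv`` by MH under its translated-beta prior (including the
    stationary-variance term of ``h_0``), and ``sigma_f^2`` from its GIG
    conditional under the Gamma(1/2, rate 1/(2 B_sv)) prior.

    Returns ``(h, phi_sv, sigma2_f, log_sd)``.
    """
    if mixture is None:
        mixture = build_log_chi2_mixture()
    J = f.shape[0]
    ystar = np.log(f**2 + _LNF2_OFFSET)
    # mixture indicators given current h
    e = ystar - state.h[1:]
    logp = (
        np.log(mixture.w)[None, :]
        - 0.5 * np.log(mixture.v)[None, :]
        - 0.5 * (e[:, None] - mixture.m[None, :]) ** 2 / mixture.v[None, :]
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    r = (rng.random(J)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    h = _ar1_ffbs(ystar, mixture.m[r], mixture.v[r], state.phi_sv, state.sigma2_f, rng)
    # phi_sv: random-walk MH on atanh(phi)
    sigma2 = state.sigma2_f

    def logpost_phi(phi: float) -> float:
        if not (-1.0 < phi < 1.0):
            return -np.inf
        trans = -0.5 * np.sum((h[1:] - phi * h[:-1]) ** 2) / sigma2
        stat = 0.5 * np.log1p(-phi**2) - 0.5 * h[0] ** 2 * (1.0 - phi**2) / sigma2
        prior = (hyper.a_sv - 1.0) * np.log((phi + 1.0) / 2.0) + (hyper.b_sv - 1.0) * np.log(
            (1.0 - phi) / 2.0
        )
        jac = np.log1p(-phi**2)  # atanh-transform Jacobian
        return trans + stat + prior + jac

    z = np.arctanh(state.phi_sv)
    zp = z + np.exp(log_sd) * rng.standard_normal()
    phi_prop = np.tanh(zp)
    accept = np.log(rng.random()) < logpost_phi(phi_prop) - logpost_phi(state.phi_sv)
    phi_sv = float(phi_prop) if accept else state.phi_sv
    state.tries_phi_sv += 1
    state.accept_phi_sv += int(accept)
    if adapt:
        log_sd += 0.05 * ((1.0 if accept else 0.0) - 0.35)
    # sigma_f^2 | h, phi_sv: GIG(-J/2, chi, 1/B_sv)
    chi = (1.0 - phi_sv**2) * h[0] ** 2 + float(np.sum((h[1:] - phi_sv * h[:-1]) ** 2))
    sigma2_f = float(sample_gig(-J / 2.0, chi, 1.0 / hyper.B_sv, rng))
    return h, phi_sv, sigma2_f, log_sd


def identify_signs(
    phi_draws: np.ndarray, f_draws: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Post-hoc sign identification: flip draws so that ``phi_1 >= 0``.

    Flipping a whole draw leaves every product ``phi_g f_j`` unchanged.
    Returns the sign-fixed copies and the count of draws with ``phi_1 = 0``
    exactly (left untouched, with a warning).
    """
    phi_draws = np.array(phi_draws, copy=True)
    f_draws = np.array(f_draws, copy=True)
    flip = phi_draws[:, 0] < 0
    phi_draws[flip] *= -1.0
    f_draws[flip] *= -1.0
    n_zero = int(np.sum(phi_draws[:, 0] == 0))
    if n_zero:
        warnings.warn(f"{n_zero} draws have phi_1 exactly 0; left unchanged", stacklevel=2)
    return phi_draws, f_draws, n_zero
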
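"""Data augmentation turning the exponential observation model Gaussian.

Each at-risk (subject, interval) pair contributes an exposure ``u_ij``.  For
pairs the subject survives (all ``j < l_i``, and ``j = l_i`` when censored)
a residual survival time ``xi_ij ~ Exp(lambda_ij)`` is added — valid by the
memorylessness of the exponential — giving total times ``tau_ij``; for an
observed failure ``tau_{i,l_i} = u_{i,l_i}`` exactly.  Then
``-ln tau_ij = z_i beta_j + eps_ij`` with standard-Gumbel noise, which the
10-component normal mixture and its component indicators ``r_ij`` convert
into the conditionally Gaussian pseudo-observations
``x_ij = -ln tau_ij - m_{r_ij}`` with variances ``v_{r_ij}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpandedData
from .gumbel import NormalMixture

__all__ = [
    "AugmentedState",
    "draw_residual_times",
    "draw_mixture_indicators",
    "build_pseudo_observations",
]


@dataclass
class AugmentedState:
    """Auxiliary variables for one sweep, aligned with the flat pair arrays."""

    tau: np.ndarray  # total survival times tau_ij
    r: np.ndarray  # mixture component indicators in 0..R-1
    x: np.ndarray  # pseudo-observations -ln tau - m_r
    v: np.ndarray  # pseudo-observation variances v_r


def draw_residual_times(
    expanded: ExpandedData, hazards: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw total survival times ``tau_ij`` for every at-risk pair.

    ``hazards`` holds ``lambda_ij > 0`` per flat pair.  Pairs flagged as an
    observed failure keep ``tau = u`` exactly; all others get an independent
    exponential residual with rate ``lambda_ij``.
    """
    hazards = np.asarray(hazards, dtype=float)
    if hazards.shape != expanded.u.shape:
        raise ValueError("hazards must align with the flat (subject, interval) pairs")
    if np.any(~(hazards > 0)):
        bad = int(np.flatnonzero(~(hazards > 0))[0])
        raise ValueError(
            f"non-positive hazard for subject {expanded.subject[bad]}, "
            f"interval {expanded.interval[bad]}"
        )
    xi = rng.exponential(1.0, size=hazards.shape) / hazards
    xi[expanded.event] = 0.0
    return expanded.u + xi


def draw_mixture_indicators(
    tau: np.ndarray,
    linpred: np.ndarray,
    mixture: NormalMixture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample component indicators ``r_ij`` given the Gumbel residuals.

    ``linpred`` is the per-pair log-hazard ``z_i beta_j`` (including any
    factor offset), so the residual is ``e_ij = -ln tau_ij - linpred_ij`` and
    ``P(r_ij = r) ∝ w_r N(e_ij; m_r, v_r)``.
    """
    e = -np.log(tau) - linpred
    if np.any(~np.isfinite(e)):
        bad = int(np.flatnonzero(~np.isfinite(e))[0])
        raise ValueError(f"non-finite Gumbel residual at flat pair {bad}")
    logp = (
        np.log(mixture.w)[None, :]
        - 0.5 * np.log(mixture.v)[None, :]
        - 0.5 * (e[:, None] - mixture.m[None, :]) ** 2 / mixture.v[None, :]
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(e.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def indicator_probabilities(e: float, mixture: NormalMixture) -> np.ndarray:
    """Normalised component probabilities for a single residual (test oracle hook)."""
    p = mixture.w * np.exp(-0.5 * (e - mixture.m) ** 2 / mixture.v) / np.sqrt(mixture.v)
    return p / p.sum()


def build_pseudo_observations(
    tau: np.ndarray, r: np.ndarray, mixture: NormalMixture
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-observations ``x_ij = -ln tau_ij - m_{r_ij}`` and variances."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("total survival times must be strictly positive")
    return -np.log(tau) - mixture.m[r], mixture.v[r]


def augment(
    expanded: ExpandedData,
    hazards: np.ndarray,
    linpred: np.ndarray,
    mixture: NormalMixture,
    rng: np.random.Generator,
) -> AugmentedState:
    """One full augmentation pass: residual times, indicators, pseudo-observations."""
    tau = draw_residual_times(expanded, hazards, rng)
    r = draw_mixture_indicators(tau, linpred, mixture, rng)
    x, v = build_pseudo_observations(tau, r, mixture)
    return AugmentedState(tau=tau, r=r, x=x, v=v)
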
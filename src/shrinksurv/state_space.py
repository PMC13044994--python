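"""Conditionally Gaussian state-space core: forward filter and FFBS.

The coefficient paths follow independent Gaussian random walks,
``beta_j = beta_{j-1} + omega_j`` with ``omega_j ~ N(0, Q)``,
``Q = diag(theta_0..theta_K)``, and the pre-sample initial state
``beta_0 ~ N(a0, P0)`` (here ``P0 = Q`` since ``beta_{k0} ~ N(beta_k, theta_k)``).
Observations per interval are ``x_j = Z_j beta_j + eps_j`` with diagonal
noise ``V_j`` from the Gumbel-mixture augmentation.

The measurement update is done in information form
(``P^-1 + Z' V^-1 Z``), which costs the same O(n_j m^2) as sequential
univariate updates, keeps the covariance symmetric by construction, and
gives the marginal log-likelihood via the Woodbury identity without ever
forming an n_j x n_j matrix.  A variance floor on the diagonal of Q keeps
the transition non-singular while the shrinkage prior pushes theta_k
towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianStateSpace", "FilterResult", "kalman_filter", "ffbs"]

_JITTER = 1e-12


@dataclass
class GaussianStateSpace:
    """Per-interval observations of a random-walk state with diagonal noise.

    ``x[j]``, ``Zmat[j]`` and ``V[j]`` hold the interval-``j+1`` observation
    vector (length ``n_j``, possibly 0), design matrix and noise variances.
    """

    x: list  # J arrays, each (n_j,)
    Zmat: list  # J arrays, each (n_j, m)
    V: list  # J arrays, each (n_j,)
    Q: np.ndarray  # (m,) state innovation variances
    a0: np.ndarray  # (m,) initial state mean
    P0: np.ndarray  # (m,) initial state variances (diagonal)
    variance_floor: float = 1e-12

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.a0 = np.asarray(self.a0, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        if np.any(self.Q < 0) or np.any(self.P0 < 0):
            raise ValueError("Q and P0 must be non-negative diagonals")
        m = self.a0.shape[0]
        for j, (xj, Zj, vj) in enumerate(zip(self.x, self.Zmat, self.V)):
            if Zj.shape != (len(xj), m) or len(vj) != len(xj):
                raise ValueError(f"inconsistent dimensions in interval {j + 1}")

    @property
    def J(self) -> int:
        return len(self.x)

    @property
    def m(self) -> int:
        return self.a0.shape[0]


@dataclass
class FilterResult:
    a_filt: np.ndarray  # (J+1, m) filtered means, index 0 = initial state
    P_filt: np.ndarray  # (J+1, m, m) filtered covariances
    loglik: float = 0.0
    Q: np.ndarray = field(default=None)


def kalman_filter(model: GaussianStateSpace, compute_loglik: bool = True) -> FilterResult:
    """Forward filter over j = 0..J; returns the Gaussian marginal log-likelihood.

    Index 0 carries the (unobserved) initial state; intervals with no
    observations perform a pure prediction step.  ``compute_loglik=False``
    skips the determinant bookkeeping (used inside MCMC sweeps, which only
    need the filtered moments).
    """
    J, m = model.J, model.m
    Q = np.maximum(model.Q, model.variance_floor)
    a = model.a0.copy()
    P = np.diag(np.maximum(model.P0, model.variance_floor)).astype(float)
    a_filt = np.empty((J + 1, m))
    P_filt = np.empty((J + 1, m, m))
    a_filt[0] = a
    P_filt[0] = P
    loglik = 0.0
    diag_ix = np.diag_indices(m)
    for j in range(1, J + 1):
        # predict (random walk)
        P = P.copy()
        P[diag_ix] += Q
        xj, Zj, vj = model.x[j - 1], model.Zmat[j - 1], model.V[j - 1]
        nj = len(xj)
        if nj:
            try:
                Pinv = np.linalg.inv(P)
                ZtVi = Zj.T / vj
                A = Pinv + ZtVi @ Zj
                A = 0.5 * (A + A.T)
                P_new = np.linalg.inv(A)
                P_new = 0.5 * (P_new + P_new.T)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"non-positive-definite innovation covariance in interval {j}; "
                    "check the variance floor configuration"
                ) from err
            rhs = Pinv @ a + ZtVi @ xj
            a = P_new @ rhs
            if compute_loglik:
                # marginal log-likelihood via Woodbury / matrix determinant lemma
                cP = np.linalg.cholesky(P)
                cA = np.linalg.cholesky(A)
                resid = xj - Zj @ a_filt[j - 1]  # predicted mean = previous filtered mean
                w = ZtVi @ resid
                quad = float(resid @ (resid / vj)) - float(w @ (P_new @ w))
                logdetP = 2.0 * np.sum(np.log(np.diag(cP)))
                logdetA = 2.0 * np.sum(np.log(np.diag(cA)))
                logdetF = float(np.sum(np.log(vj))) + logdetP + logdetA
                loglik += -0.5 * (nj * np.log(2 * np.pi) + logdetF + quad)
            P = P_new
        a_filt[j] = a
        P_filt[j] = P
    return FilterResult(a_filt=a_filt, P_filt=P_filt, loglik=loglik, Q=Q)


def _chol_psd(P: np.ndarray) -> np.ndarray:
    P = 0.5 * (P + P.T)
    try:
        return np.linalg.cholesky(P + _JITTER * np.eye(P.shape[0]))
    except np.linalg.LinAlgError:
        # fall back to an eigenvalue square root for numerically semidefinite P
        vals, vecs = np.linalg.eigh(P)
        return vecs * np.sqrt(np.maximum(vals, 0.0))


def ffbs(
    model: GaussianStateSpace,
    rng: np.random.Generator,
    size: int | None = None,
    filt: FilterResult | None = None,
) -> np.ndarray:
    """Forward-filtering backward-sampling draw of the full state path.

    Returns an exact joint draw of ``beta_{0:J}`` from its conditional given
    the observations, innovation variances and initial moments.  With
    ``size`` set, that many independent paths are drawn from one forward
    pass (vectorised backward pass), shape ``(size, J+1, m)``.
    """
    if filt is None:
        filt = kalman_filter(model, compute_loglik=False)
    J, m = model.J, model.m
    Q = filt.Q
    squeeze = size is None
    S = 1 if squeeze else int(size)
    beta = np.empty((S, J + 1, m))
    L = _chol_psd(filt.P_filt[J])
    beta[:, J] = filt.a_filt[J] + rng.standard_normal((S, m)) @ L.T
    for j in range(J - 1, -1, -1):
        Pj = filt.P_filt[j]
        Ppred = Pj + np.diag(Q)
        G = np.linalg.solve(Ppred.T, Pj.T).T  # P_j (P_j + Q)^-1
        cond_cov = Pj - G @ Pj
        mean = filt.a_filt[j] + (beta[:, j + 1] - filt.a_filt[j]) @ G.T
        L = _chol_psd(cond_cov)
        beta[:, j] = mean + rng.standard_normal((S, m)) @ L.T
    return beta[0] if squeeze else beta
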
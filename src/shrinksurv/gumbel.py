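"""Normal-mixture approximations used by the data augmentation.

Taking logs of the conditionally exponential observation equation of the
piecewise-exponential model yields ``-ln tau_ij = z_i beta_j + eps_ij`` with
``eps_ij`` standard Gumbel, density ``p(e) = exp(-e - exp(-e))``.  A
10-component normal mixture approximates that distribution very closely and
turns the model conditionally Gaussian once component indicators are
introduced.  The same machinery provides the auxiliary mixture for
``ln chi^2_1`` used by the stochastic-volatility block.

The component constants are obtained by minimising the Kullback-Leibler
divergence KL(p || q) on a fixed quadrature grid — equivalently, by a
weighted EM fit of the mixture to the target density — and cached as a
plain-text package data file so the approximation is reproducible.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "NormalMixture",
    "build_gumbel_mixture",
    "build_log_chi2_mixture",
    "fit_mixture_to_density",
    "EULER_GAMMA",
    "GUMBEL_VARIANCE",
]

EULER_GAMMA = 0.5772156649015329
GUMBEL_VARIANCE = math.pi**2 / 6.0

_TABLE_DIR = "_tables"


@dataclass(frozen=True)
class NormalMixture:
    """A finite mixture of normals with weights ``w``, means ``m``, variances ``v``."""

    w: np.ndarray
    m: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w", "m", "v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.w.shape == self.m.shape == self.v.shape):
            raise ValueError("w, m, v must have identical shapes")
        if np.any(self.w <= 0) or np.any(self.v <= 0):
            raise ValueError("weights and variances must be strictly positive")
        if abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to one")

    @property
    def n_components(self) -> int:
        return self.w.shape[0]

    def mean(self) -> float:
        return float(np.sum(self.w * self.m))

    def var(self) -> float:
        mu = self.mean()
        return float(np.sum(self.w * (self.v + (self.m - mu) ** 2)))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        return np.sum(self.w * norm.cdf(x, loc=self.m, scale=np.sqrt(self.v)), axis=-1)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = (
            np.log(self.w)
            - 0.5 * np.log(2 * np.pi * self.v)
            - 0.5 * (x - self.m) ** 2 / self.v
        )
        return logsumexp(comp, axis=-1)


def gumbel_logpdf(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -x - np.exp(-x)


def gumbel_cdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-np.exp(-np.asarray(x, dtype=float)))


def log_chi2_logpdf(x: np.ndarray) -> np.ndarray:
    """Density of ``ln Z`` with ``Z ~ chi^2_1``."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (x - np.exp(x)) - 0.5 * math.log(2 * math.pi)


def fit_mixture_to_density(
    logpdf,
    n_components: int,
    grid_lo: float,
    grid_hi: float,
    n_grid: int = 4001,
    n_iter: int = 5000,
    tol: float = 1e-12,
) -> NormalMixture:
    """Fit a normal mixture to a target density by weighted EM on a quadrature grid.

    Maximising the grid-weighted log-likelihood is, up to a constant, the
    same as minimising KL(p || q), where p is the target and q the mixture.
    Deterministic initialisation (means at equally spaced target quantiles)
    makes the fit reproducible without any randomness.
    """
    x = np.linspace(grid_lo, grid_hi, n_grid)
    lp = logpdf(x)
    wts = np.exp(lp - logsumexp(lp))
    mu_target = float(np.sum(wts * x))
    var_target = float(np.sum(wts * (x - mu_target) ** 2))
    # deterministic init: means at equally spaced quantiles of the target
    cdf = np.cumsum(wts)
    probs = (np.arange(n_components) + 0.5) / n_components
    m = np.interp(probs, cdf, x)
    v = np.full(n_components, var_target / n_components)
    w = np.full(n_components, 1.0 / n_components)
    prev = -np.inf
    for _ in range(n_iter):
        comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * v)[None, :]
            - 0.5 * (x[:, None] - m[None, :]) ** 2 / v[None, :]
        )
        norm_c = logsumexp(comp, axis=1)
        ll = float(np.sum(wts * norm_c))
        resp = np.exp(comp - norm_c[:, None]) * wts[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / nk.sum()
        m = (resp * x[:, None]).sum(axis=0) / nk
        v = (resp * (x[:, None] - m[None, :]) ** 2).sum(axis=0) / nk
        v = np.maximum(v, 1e-10)
        if ll - prev < tol and ll >= prev:
            break
        prev = ll
    order = np.argsort(m)[::-1]
    return NormalMixture(w=w[order], m=m[order], v=v[order])


def _validate_gumbel(mix: NormalMixture) -> None:
    if mix.n_components != 10:
        raise ValueError("the Gumbel approximation must have 10 components")
    if abs(mix.mean() - EULER_GAMMA) > 0.01:
        raise ValueError(f"mixture mean {mix.mean():.5f} misses the Gumbel mean {EULER_GAMMA:.5f}")
    if abs(mix.var() - GUMBEL_VARIANCE) > 0.02:
        raise ValueError(f"mixture variance {mix.var():.5f} misses pi^2/6 = {GUMBEL_VARIANCE:.5f}")
    grid = np.linspace(-8.0, 15.0, 2001)
    sup = float(np.max(np.abs(mix.cdf(grid) - gumbel_cdf(grid))))
    if sup > 0.01:
        raise ValueError(f"CDF sup-distance {sup:.4f} to the standard Gumbel exceeds 0.01")


def _table_path(name: str) -> Path:
    return Path(importlib.resources.files("shrinksurv").joinpath(_TABLE_DIR, name))


def _load_table(name: str) -> NormalMixture:
    path = _table_path(name)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return NormalMixture(w=arr[:, 1], m=arr[:, 2], v=arr[:, 3])


def _save_table(mix: NormalMixture, name: str) -> None:
    path = _table_path(name)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = np.column_stack([np.arange(1, mix.n_components + 1), mix.w, mix.m, mix.v])
    np.savetxt(path, rows, delimiter=",", header="r,w,m,v", comments="", fmt="%.17g")


def build_gumbel_mixture(source: str = "kl_fit") -> NormalMixture:
    """Return the 10-component normal approximation to the standard Gumbel.

    ``source="kl_fit"`` (default) loads the cached KL-fitted constants,
    refitting (and caching, where the package directory is writable) if the
    cache is absent.  ``source="table"`` loads the shipped constants file
    directly and fails if it is missing.
    """
    if source == "table":
        mix = _load_table("gumbel10.csv")
        _validate_gumbel(mix)
        return mix
    if source != "kl_fit":
        raise ValueError("source must be 'kl_fit' or 'table'")
    try:
        mix = _load_table("gumbel10.csv")
    except OSError:
        mix = fit_mixture_to_density(gumbel_logpdf, 10, -10.0, 15.0)
        try:
            _save_table(mix, "gumbel10.csv")
        except OSError:
            pass
    _validate_gumbel(mix)
    return mix


def build_log_chi2_mixture(source: str = "kl_fit") -> NormalMixture:
    """10-component normal approximation to ``ln chi^2_1`` (SV auxiliary mixture)."""
    if source == "table":
        return _load_table("logchi2_10.csv")
    if source != "kl_fit":
        raise ValueError("source must be 'kl_fit' or 'table'")
    try:
        return _load_table("logchi2_10.csv")
    except OSError:
        mix = fit_mixture_to_density(log_chi2_logpdf, 10, -40.0, 8.0, n_grid=8001)
        try:
            _save_table(mix, "logchi2_10.csv")
        except OSError:
            pass
        return mix
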
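"""Bifurcating autoregression of cell-cycle-phase durations.

Each phase (G1 and S/G2/M, modelled independently) follows a first-order
autoregression on the binary lineage tree: both progeny of a parent with
phase duration T receive

    T_i = m + theta (T - m) + W_i,        i = 1, 2,

where (W_1, W_2) is an exchangeable bivariate lognormal pair — the
component-wise exponential of a bivariate normal with common mean ``mu``,
common variance ``sigma2`` and correlation ``rho``.  The lognormal noise
keeps durations positively skewed and bounded away from symmetry, which
Gaussian noise cannot do.

Closed-form equilibrium moments of the stationary duration distribution:

    E(T)        = m + e^{mu + sigma2/2} / (1 - theta)
    Var(T)      = e^{2 mu} e^{sigma2} (e^{sigma2} - 1) / (1 - theta^2)
    corr(T1,T2) = theta^2 + (1 - theta^2) (e^{rho sigma2}-1)/(e^{sigma2}-1)
    corr(Ti,T)  = theta            (parent-progeny)
    corr cousins = corr(T1,T2) * theta^2

(cousins are linked through the chain cousin-parent-parent-cousin, so
their covariance is theta^2 times the sibling covariance of the parent
generation; each generation of separation costs one factor of theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BifurcatingARParams",
    "lognormal_pair_correlation",
    "draw_sibling_noise",
    "progeny_phase_durations",
    "stationary_moments",
    "stationary_sample",
]


@dataclass(frozen=True)
class BifurcatingARParams:
    """Inheritance parameters of one phase.

    m       location constant, hours (phase mean plus the corrective term
            that fixes the equilibrium mean)
    theta   inherited fraction, dimensionless, theta^2 < 1
    mu      log-scale mean of the noise
    sigma2  log-scale variance of the noise, > 0
    rho     correlation of the underlying normal pair, in (-1, 1]
    """

    m: float
    theta: float
    mu: float
    sigma2: float
    rho: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not self.theta**2 < 1:
            raise ValueError(f"need theta^2 < 1 for equilibrium, got theta={self.theta}")
        if not (-1 < self.rho <= 1):
            raise ValueError(f"rho must lie in (-1, 1], got {self.rho}")

    @classmethod
    def from_target_mean(
        cls, mean: float, theta: float, mu: float, sigma2: float, rho: float = 0.0
    ) -> "BifurcatingARParams":
        """Build params with ``m`` chosen so the equilibrium mean equals ``mean``."""
        m = mean - np.exp(mu + sigma2 / 2) / (1 - theta)
        return cls(m=m, theta=theta, mu=mu, sigma2=sigma2, rho=rho)


def lognormal_pair_correlation(sigma2: float, rho: float) -> float:
    """corr(W1, W2) = (e^{rho sigma2} - 1)/(e^{sigma2} - 1)."""
    return np.expm1(rho * sigma2) / np.expm1(sigma2)


def draw_sibling_noise(
    params: BifurcatingARParams, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw exchangeable bivariate lognormal noise pairs.

    Returns shape (2,) for ``size=None`` else (size, 2).  Both marginals
    are lognormal(mu, sigma2); the underlying normal pair has correlation
    rho.
    """
    n = 1 if size is None else int(size)
    sd = np.sqrt(params.sigma2)
    if params.rho == 1.0:
        z = rng.standard_normal((n, 1))
        x = np.repeat(z, 2, axis=1)
    else:
        # X1 = Z0, X2 = rho Z0 + sqrt(1-rho^2) Z1
        z = rng.standard_normal((n, 2))
        x = np.empty_like(z)
        x[:, 0] = z[:, 0]
        x[:, 1] = params.rho * z[:, 0] + np.sqrt(1 - params.rho**2) * z[:, 1]
    w = np.exp(params.mu + sd * x)
    return w[0] if size is None else w


def progeny_phase_durations(
    parent_T: float,
    params: BifurcatingARParams,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Durations of the two progeny given the parent's duration.

    The sibling pair shares one noise draw.  Non-positive durations (only
    possible when theta (T - m) is very negative) trigger a redraw of the
    noise pair, up to ``max_redraws`` attempts.
    """
    if parent_T <= 0:
        raise ValueError(f"parent duration must be > 0, got {parent_T}")
    base = params.m + params.theta * (parent_T - params.m)
    for _ in range(max_redraws):
        w = draw_sibling_noise(params, rng)
        t1, t2 = base + w[0], base + w[1]
        if t1 > 0 and t2 > 0:
            return float(t1), float(t2)
    raise RuntimeError(
        f"could not draw positive progeny durations after {max_redraws} attempts "
        f"(parent_T={parent_T}, params={params})"
    )


def stationary_moments(params: BifurcatingARParams) -> dict[str, float]:
    """Equilibrium mean/variance and family correlations.

    Returns ``{"mean", "variance", "rho_sib", "rho_parent", "rho_cousin"}``.
    """
    th = params.theta
    if th**2 >= 1:
        raise ValueError("theta^2 >= 1: no equilibrium exists")
    mean = params.m + np.exp(params.mu + params.sigma2 / 2) / (1 - th)
    var = (
        np.exp(2 * params.mu)
        * np.exp(params.sigma2)
        * np.expm1(params.sigma2)
        / (1 - th**2)
    )
    rho_sib = th**2 + (1 - th**2) * lognormal_pair_correlation(params.sigma2, params.rho)
    return {
        "mean": float(mean),
        "variance": float(var),
        "rho_sib": float(rho_sib),
        "rho_parent": float(th),
        "rho_cousin": float(rho_sib * th**2),
    }


def stationary_sample(
    params: BifurcatingARParams,
    rng: np.random.Generator,
    size: int,
    tol: float = 1e-12,
) -> np.ndarray:
    """Draw from the equilibrium duration distribution.

    Uses the moving-average representation T = m + sum_k theta^k W_k with
    the series truncated once theta^k falls below ``tol`` relative to the
    leading term (exact for theta = 0).  Marginal only — draws are
    independent across the returned vector.
    """
    th = abs(params.theta)
    if th == 0:
        k_max = 1
    else:
        k_max = max(1, int(np.ceil(np.log(tol) / np.log(th))) + 1)
    sd = np.sqrt(params.sigma2)
    w = np.exp(params.mu + sd * rng.standard_normal((size, k_max)))
    weights = params.theta ** np.arange(k_max)
    return params.m + w @ weights
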
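"""Method-of-moments estimation of phase-duration inheritance.

Given pedigree phase durations at equilibrium, the estimator inverts the
closed-form moment relations of the bifurcating autoregression:

    theta_hat  = rho_hat(parent, progeny)
    A_hat      = (rho_hat(sib) - theta_hat^2) / (1 - theta_hat^2)
    x0 solves  x^rho - 1 = A_hat (x - 1),  x = e^{sigma2} > 1   (rho > A_hat)
    sigma2_hat = ln x0
    mu_hat     = 0.5 ln[ Var_hat (1 - theta_hat^2) / (e^{s2}(e^{s2}-1)) ]
    m_hat      = E_hat - e^{mu_hat + sigma2_hat/2} / (1 - theta_hat)

``rho`` (the latent noise correlation) is not identified by the first two
moments alone; it is either supplied or profiled over a grid, choosing
the value whose implied equilibrium distribution is closest (in
Kolmogorov-Smirnov distance) to the observed durations.

The user-facing entry point is :class:`BifurcatingAutoregression`, a
model object built from a pedigree whose ``fit`` returns a
:class:`BifurcatingARResults` with parameter estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bifurcating import (
    BifurcatingARParams,
    stationary_moments,
    stationary_sample,
)
from .pedigree import Pedigree, extract_pairs

__all__ = [
    "PedigreeMoments",
    "EstimationResult",
    "compute_pedigree_moments",
    "solve_sigma2",
    "estimate_params",
    "profile_rho",
    "correlation_se_mccv",
    "BifurcatingAutoregression",
    "BifurcatingARResults",
]

_PHASE_FIELD = {"g1": "t_g1", "sg2m": "t_sg2m", "cycle": "t_cycle"}


class EstimationError(ValueError):
    pass


@dataclass
class PedigreeMoments:
    """Sample moments of one phase's durations and family correlations."""

    mean_T: float
    var_T: float
    rho_sib_hat: float
    rho_parent_hat: float
    n_cells: int
    n_sib_pairs: int
    n_pp_pairs: int
    rho_cousin_hat: float | None = None
    n_cousin_pairs: int = 0


@dataclass
class EstimationResult:
    """Point estimates plus solver diagnostics."""

    params: BifurcatingARParams
    a_hat: float
    x0: float
    rho: float
    diagnostics: dict = field(default_factory=dict)


def _symmetrized_corr(pairs: list[tuple[float, float]]) -> float:
    """Pearson correlation with each unordered pair counted in both orders.

    The exchangeable-pair (intraclass) convention: makes the estimate
    invariant to the arbitrary labelling of siblings/cousins.
    """
    a = np.asarray(pairs, dtype=float)
    x = np.concatenate([a[:, 0], a[:, 1]])
    y = np.concatenate([a[:, 1], a[:, 0]])
    sx = x.std()
    if sx == 0 or y.std() == 0:
        raise EstimationError("degenerate variance in pair values")
    return float(np.corrcoef(x, y)[0, 1])


def _plain_corr(pairs: list[tuple[float, float]]) -> float:
    a = np.asarray(pairs, dtype=float)
    if a[:, 0].std() == 0 or a[:, 1].std() == 0:
        raise EstimationError("degenerate variance in pair values")
    return float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])


def compute_pedigree_moments(
    pedigree: Pedigree, phase: str = "cycle", include_cousins: bool = False
) -> PedigreeMoments:
    """First and second moments plus sibling / parent-progeny correlations.

    Sibling (and cousin) correlations use the symmetrized-pair convention;
    parent-progeny correlation uses all (parent, progeny) pairs as
    ordered pairs.
    """
    if phase not in _PHASE_FIELD:
        raise ValueError(f"unknown phase {phase!r}; expected one of {sorted(_PHASE_FIELD)}")
    fieldname = _PHASE_FIELD[phase]
    values = np.array([getattr(c, fieldname) for c in pedigree.cells()], dtype=float)
    if len(values) < 2:
        raise EstimationError("need at least 2 cells")
    var = float(values.var(ddof=1))
    if var == 0:
        raise EstimationError("degenerate variance: all durations identical")

    sib = extract_pairs(pedigree, "sibling", fieldname)
    if not sib:
        raise EstimationError("no sibling pairs in pedigree")
    pp = extract_pairs(pedigree, "parent_progeny", fieldname)
    if not pp:
        raise EstimationError("no parent-progeny pairs in pedigree")

    rho_cousin = None
    n_cousin = 0
    if include_cousins:
        cous = extract_pairs(pedigree, "cousin", fieldname)
        n_cousin = len(cous)
        if cous:
            rho_cousin = _symmetrized_corr(cous)

    return PedigreeMoments(
        mean_T=float(values.mean()),
        var_T=var,
        rho_sib_hat=_symmetrized_corr(sib),
        rho_parent_hat=_plain_corr(pp),
        n_cells=len(values),
        n_sib_pairs=len(sib),
        n_pp_pairs=len(pp),
        rho_cousin_hat=rho_cousin,
        n_cousin_pairs=n_cousin,
    )


def solve_sigma2(a_hat: float, rho: float, x_cap: float = 1e12, tol: float = 1e-13) -> tuple[float, float]:
    """Solve x^rho - 1 = A_hat (x - 1) for x = e^{sigma2} > 1.

    For 0 < A_hat < rho <= 1 the function f(x) = x^rho - 1 - A_hat(x-1)
    is positive just above 1 and eventually negative, with a single root
    x0 > 1.  Bracketing grows geometrically up to ``x_cap``; bisection
    then locates the root.  Returns ``(sigma2, x0)``.
    """
    if not 0 < a_hat < 1:
        raise EstimationError(f"A_hat must lie in (0,1), got {a_hat}")
    if rho <= a_hat:
        raise EstimationError(
            f"no root > 1 exists: need rho > A_hat (rho={rho}, A_hat={a_hat})"
        )
    if rho == 1.0:
        raise EstimationError("rho = 1 makes the equation degenerate (sigma2 unidentified)")

    def f(x):
        return x**rho - 1.0 - a_hat * (x - 1.0)

    lo = 1.0 + 1e-12
    hi = 2.0
    while f(hi) > 0:
        hi *= 4.0
        if hi > x_cap:
            raise EstimationError(
                f"no sign change found up to x_cap={x_cap:g}; rho is too close to A_hat"
            )
    # bisection: f(lo) > 0, f(hi) <= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    x0 = 0.5 * (lo + hi)
    return float(np.log(x0)), float(x0)


def estimate_params(moments: PedigreeMoments, rho: float) -> EstimationResult:
    """Invert the equilibrium moment relations at an assumed noise correlation."""
    theta = moments.rho_parent_hat
    if theta**2 >= 1:
        raise EstimationError(f"|parent-progeny correlation| >= 1 ({theta})")
    a_hat = (moments.rho_sib_hat - theta**2) / (1 - theta**2)
    if a_hat <= 0:
        raise EstimationError(
            "sibling correlation below theta^2 - model misspecified or noise "
            f"(rho_sib={moments.rho_sib_hat:.4f}, theta^2={theta**2:.4f})"
        )
    if a_hat >= 1:
        raise EstimationError(f"A_hat >= 1 ({a_hat:.4f}); sibling correlation too large")
    sigma2, x0 = solve_sigma2(a_hat, rho)
    mu = 0.5 * np.log(
        moments.var_T * (1 - theta**2) / (np.exp(sigma2) * np.expm1(sigma2))
    )
    m = moments.mean_T - np.exp(mu + sigma2 / 2) / (1 - theta)
    params = BifurcatingARParams(m=float(m), theta=float(theta), mu=float(mu),
                                 sigma2=float(sigma2), rho=float(rho))
    return EstimationResult(params=params, a_hat=float(a_hat), x0=x0, rho=float(rho))


def profile_rho(
    pedigree: Pedigree,
    phase: str,
    rho_grid,
    rng: np.random.Generator | None = None,
    n_ref: int = 100_000,
) -> EstimationResult:
    """Profile the unidentified noise correlation over a grid.

    For each feasible rho the moment inversion is carried out and the
    Kolmogorov-Smirnov distance between the observed durations and an
    ``n_ref``-sample draw from the implied equilibrium distribution is
    recorded; the rho with the smallest distance wins.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    moments = compute_pedigree_moments(pedigree, phase)
    fieldname = _PHASE_FIELD[phase]
    observed = np.array([getattr(c, fieldname) for c in pedigree.cells()], dtype=float)
    best: EstimationResult | None = None
    scores: dict[float, float] = {}
    for rho in np.atleast_1d(np.asarray(rho_grid, dtype=float)):
        try:
            res = estimate_params(moments, float(rho))
        except EstimationError:
            continue
        ref = stationary_sample(res.params, rng, n_ref)
        ks = stats.ks_2samp(observed, ref).statistic
        scores[float(rho)] = float(ks)
        if best is None or ks < best.diagnostics["ks"]:
            res.diagnostics["ks"] = float(ks)
            best = res
    if best is None:
        raise EstimationError("no feasible rho in grid (all rho <= A_hat or inversion failed)")
    best.diagnostics["ks_by_rho"] = scores
    return best


def correlation_se_mccv(
    pairs: list[tuple[float, float]],
    rng: np.random.Generator,
    n_iter: int = 1000,
    holdout: float = 0.5,
    symmetrize: bool = True,
) -> float:
    """Monte Carlo cross-validation standard error of a pair correlation.

    Repeatedly recomputes the correlation on random subsets containing a
    ``holdout`` fraction of the pairs and reports the standard deviation
    across iterations.
    """
    a = np.asarray(pairs, dtype=float)
    n = len(a)
    k = max(3, int(round(holdout * n)))
    est = _symmetrized_corr if symmetrize else _plain_corr
    vals = []
    for _ in range(n_iter):
        idx = rng.choice(n, size=k, replace=False)
        try:
            vals.append(est([tuple(p) for p in a[idx]]))
        except EstimationError:
            continue
    return float(np.std(vals))


# ---------------------------------------------------------------------------
# model / results objects


class BifurcatingAutoregression:
    """Bifurcating-autoregression model of one phase, built from a pedigree.

    Parameters
    ----------
    pedigree : Pedigree
        Observed lineage forest with per-cell phase durations.
    phase : {"g1", "sg2m", "cycle"}
        Which duration to model.  G1 and S/G2/M are independent models.

    ``fit(rho=...)`` inverts the equilibrium moments at a fixed noise
    correlation; ``fit(rho_grid=...)`` profiles it.
    """

    def __init__(self, pedigree: Pedigree, phase: str = "cycle"):
        if phase not in _PHASE_FIELD:
            raise ValueError(f"unknown phase {phase!r}")
        self.pedigree = pedigree
        self.phase = phase
        self.moments = compute_pedigree_moments(pedigree, phase, include_cousins=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phase: str = "cycle") -> "BifurcatingAutoregression":
        return cls(Pedigree.from_dataframe(df), phase=phase)

    def fit(
        self,
        rho: float | None = None,
        rho_grid=None,
        rng: np.random.Generator | None = None,
        se_iterations: int = 0,
    ) -> "BifurcatingARResults":
        if (rho is None) == (rho_grid is None):
            raise ValueError("pass exactly one of rho / rho_grid")
        if rho is not None:
            res = estimate_params(self.moments, rho)
        else:
            res = profile_rho(self.pedigree, self.phase, rho_grid, rng=rng)
        ses = None
        if se_iterations > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            fieldname = _PHASE_FIELD[self.phase]
            ses = {
                "rho_sib_hat": correlation_se_mccv(
                    extract_pairs(self.pedigree, "sibling", fieldname),
                    rng, n_iter=se_iterations),
                "rho_parent_hat": correlation_se_mccv(
                    extract_pairs(self.pedigree, "parent_progeny", fieldname),
                    rng, n_iter=se_iterations, symmetrize=False),
            }
        return BifurcatingARResults(self, res, correlation_ses=ses)


class BifurcatingARResults:
    """Fit results: parameter estimates, diagnostics, summary table."""

    def __init__(
        self,
        model: BifurcatingAutoregression,
        estimation: EstimationResult,
        correlation_ses: dict | None = None,
    ):
        self.model = model
        self.estimation = estimation
        self.params = estimation.params
        self.a_hat = estimation.a_hat
        self.x0 = estimation.x0
        self.rho = estimation.rho
        self.correlation_ses = correlation_ses

    @property
    def fitted_moments(self) -> dict[str, float]:
        """Equilibrium moments implied by the estimates (inversion check)."""
        return stationary_moments(self.params)

    def simulate_equilibrium(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return stationary_sample(self.params, rng, size)

    def summary(self) -> str:
        mom = self.model.moments
        fit = self.fitted_moments
        p = self.params
        lines = [
            "Bifurcating autoregression - method of moments",
            "=" * 54,
            f"phase: {self.model.phase:<6}  cells: {mom.n_cells}  "
            f"sib pairs: {mom.n_sib_pairs}  pp pairs: {mom.n_pp_pairs}",
            "-" * 54,
            f"{'':18}{'estimate':>12}",
            f"{'m (h)':18}{p.m:>12.4f}",
            f"{'theta':18}{p.theta:>12.4f}",
            f"{'mu (log h)':18}{p.mu:>12.4f}",
            f"{'sigma2':18}{p.sigma2:>12.4f}",
            f"{'rho (assumed)':18}{p.rho:>12.4f}",
            f"{'A_hat':18}{self.a_hat:>12.4f}",
            f"{'x0':18}{self.x0:>12.4f}",
            "-" * 54,
            f"{'moment':18}{'sample':>12}{'fitted':>12}",
            f"{'mean (h)':18}{mom.mean_T:>12.4f}{fit['mean']:>12.4f}",
            f"{'variance (h^2)':18}{mom.var_T:>12.4f}{fit['variance']:>12.4f}",
            f"{'rho sibling':18}{mom.rho_sib_hat:>12.4f}{fit['rho_sib']:>12.4f}",
            f"{'rho parent':18}{mom.rho_parent_hat:>12.4f}{fit['rho_parent']:>12.4f}",
        ]
        if mom.rho_cousin_hat is not None:
            lines.append(
                f"{'rho cousin':18}{mom.rho_cousin_hat:>12.4f}{fit['rho_cousin']:>12.4f}"
            )
        if self.correlation_ses:
            lines.append("-" * 54)
            for k, v in self.correlation_ses.items():
                lines.append(f"{'se ' + k:18}{v:>12.4f}")
        if "ks" in self.estimation.diagnostics:
            lines.append(f"{'KS (profile)':18}{self.estimation.diagnostics['ks']:>12.4f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<BifurcatingARResults phase={self.model.phase} theta={self.params.theta:.3f} "
                f"sigma2={self.params.sigma2:.3f}>")
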
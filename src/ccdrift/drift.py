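"""Wright-Fisher-style drift analysis of simulated populations.

A population grown from N ancestors is summarised by the vector of
per-ancestor descendant fractions at an analysis time.  If those
fractions behaved like a Wright-Fisher population of effective size K,
the scaled counts X = Y * K would be multinomial MN(1/N, ...; K), giving

    E(Y_i) = 1/N,   Var(Y_i) = (N-1) N^-2 K^-1,
    Cov(Y_i, Y_j) = -N^-2 K^-1,   rho(Y_i, Y_j) = -1/(N-1).

Inverting the variance relation yields the moment estimator
K_hat = (N-1) / (N^2 V_hat) from the across-replicate fraction variance.
The classical harmonic-mean law for varying census size provides the
no-correlation benchmark:

    K = { dt^-1 \\int_0^dt [N(tau)]^-1 dtau }^-1
      = N_0 N_T / (N_T - N_0) * ln(N_T / N_0)   (exponential growth).

Family correlations shrink K below the harmonic mean: heritable timing
lets one lineage's luck persist, which is exactly stronger drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .bifurcating import BifurcatingARParams, stationary_moments
from .estimation import EstimationError, solve_sigma2
from .pedigree import CensusSeries
from .population import SimulationConfig, branching_census, malthusian_rate

__all__ = [
    "DriftReplicateSet",
    "EffectiveSizeResult",
    "k_from_fraction_variance",
    "effective_size",
    "multinomial_expectations",
    "harmonic_mean_k",
    "compare_to_binomial",
    "simulate_fraction_replicates",
    "ar_params_for_targets",
    "correlation_sweep",
]


@dataclass
class DriftReplicateSet:
    """Per-ancestor descendant fractions across replicate simulations.

    ``fractions`` is an (M, N) matrix; each row sums to 1.
    """

    fractions: np.ndarray
    analysis_time: float

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[0] < 2:
            raise ValueError("need an (M >= 2, N) fraction matrix")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")

    @property
    def n_ancestors(self) -> int:
        return self.fractions.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.fractions.shape[0]


@dataclass
class EffectiveSizeResult:
    """Moment-based effective size and the underlying statistics."""

    k_hat: float
    s_r2: float
    s_c2: float
    var_hat: float
    cov_hat: float
    rho_hat: float
    n_ancestors: int
    n_replicates: int

    def summary(self) -> str:
        exp = multinomial_expectations(self.n_ancestors, self.k_hat)
        return "\n".join(
            [
                "Effective population size (fraction-variance inversion)",
                "=" * 56,
                f"N ancestors {self.n_ancestors}   M replicates {self.n_replicates}",
                f"{'K_hat':26}{self.k_hat:>12.2f}",
                f"{'S_r^2':26}{self.s_r2:>12.6g}",
                f"{'S_c^2':26}{self.s_c2:>12.6g}",
                f"{'Var_hat(Y_i)':26}{self.var_hat:>12.6g}",
                f"{'Cov_hat(Y_i,Y_j)':26}{self.cov_hat:>12.6g}",
                f"{'rho_hat':26}{self.rho_hat:>12.3f}",
                f"{'rho expected (-1/(N-1))':26}{exp['rho']:>12.3f}",
            ]
        )


def k_from_fraction_variance(N: int, var_y: float) -> float:
    """Invert Var(Y_i) = (N-1) N^-2 K^-1 for the effective size K."""
    if N < 2:
        raise ValueError("need N >= 2 ancestors")
    if var_y <= 0:
        raise ValueError("degenerate: zero fraction variance, K unbounded")
    return (N - 1) / (N**2 * var_y)


def effective_size(reps: DriftReplicateSet) -> EffectiveSizeResult:
    """Moment estimator of K from replicate descendant fractions.

    V_hat is the across-replicate variance of fractions centred on the
    per-ancestor means (ancestors are exchangeable, so the per-ancestor
    centring only removes finite-M noise); K_hat = (N-1)/(N^2 V_hat).
    The raw statistics S_r^2 (centred on 1/N) and S_c^2 (centred per
    ancestor) give the exchangeable moment estimates of Var and Cov:
    E(S_r^2) = Var - Cov and E(S_c^2) = Var (up to the M/(M-1) factor).
    """
    y = reps.fractions
    m, n = y.shape
    ybar = y.mean(axis=0)
    s_r2 = float(((y - 1.0 / n) ** 2).mean())
    s_c2 = float(((y - ybar) ** 2).mean())
    # Caveat on cov_hat/rho_hat: because every fraction row sums to one,
    # the negative cross-correlation between ancestors is absorbed by the
    # centring and S_c2 ~ S_r2 up to O(1/M); the moment covariance
    # therefore sits near 0 rather than at the closed form -1/(N^2 K).
    # K itself is unaffected (it uses the variance only).
    var_hat = s_c2 * m / (m - 1)
    if var_hat <= 0:
        raise ValueError("degenerate: zero fraction variance, K unbounded")
    cov_hat = var_hat - s_r2 * m / (m - 1)
    k_hat = k_from_fraction_variance(n, var_hat)
    return EffectiveSizeResult(
        k_hat=float(k_hat),
        s_r2=s_r2,
        s_c2=s_c2,
        var_hat=float(var_hat),
        cov_hat=float(cov_hat),
        rho_hat=float(cov_hat / var_hat),
        n_ancestors=n,
        n_replicates=m,
    )


def multinomial_expectations(N: int, K: float) -> dict[str, float]:
    """Closed-form Wright-Fisher moments of scaled fractions Y = X/K."""
    if N < 2:
        raise ValueError("need N >= 2 ancestors")
    if K <= 0:
        raise ValueError("need K > 0")
    var = (N - 1) / (N**2 * K)
    cov = -1.0 / (N**2 * K)
    return {"e_y": 1.0 / N, "var_y": var, "cov_y": cov, "rho": -1.0 / (N - 1)}


def harmonic_mean_k(
    census: CensusSeries, dt_window: tuple[float, float] | None = None
) -> dict[str, float]:
    """Harmonic-mean effective size over a census window.

    Returns both the integral estimate (trapezoid on the census grid of
    1/N(tau)) and the exponential-growth closed form
    N0 NT/(NT - N0) ln(NT/N0); for clean exponential growth they agree
    within a few percent.  For constant census both reduce to N.
    """
    t = census.times
    n = census.total
    if dt_window is None:
        dt_window = (float(t[0]), float(t[-1]))
    lo, hi = dt_window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"window {dt_window} outside census range ({t[0]}, {t[-1]})")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    tt, nn = t[mask], n[mask]
    if np.any(nn < 1):
        raise ValueError("census counts must be >= 1")
    integral = np.trapezoid(1.0 / nn, tt) / (tt[-1] - tt[0])
    k_integral = 1.0 / integral
    n0, nt = float(nn[0]), float(nn[-1])
    if np.isclose(n0, nt):
        k_closed = n0
    else:
        k_closed = n0 * nt / (nt - n0) * np.log(nt / n0)
    return {"k_integral": float(k_integral), "k_closed_form": float(k_closed)}


def compare_to_binomial(
    reps: DriftReplicateSet,
    k_hat: float,
    rng: np.random.Generator,
) -> dict:
    """Rank-test comparison of scaled fractions against Binom(1/N; K).

    Pools all M x N scaled fractions X = Y * K_hat and draws an
    equal-size fresh sample from Binom(round(K_hat), 1/N); returns both
    empirical CDFs and the two-sample Wilcoxon (Mann-Whitney) p-value.
    """
    n = reps.n_ancestors
    x = (reps.fractions * k_hat).ravel()
    k_int = max(1, int(round(k_hat)))
    ref = rng.binomial(k_int, 1.0 / n, size=x.size).astype(float)
    test = stats.mannwhitneyu(x, ref, alternative="two-sided")
    xs = np.sort(x)
    rs = np.sort(ref)
    cdf = np.arange(1, x.size + 1) / x.size
    return {
        "p_value": float(test.pvalue),
        "statistic": float(test.statistic),
        "cdf_model": (xs, cdf),
        "cdf_binomial": (rs, cdf),
    }


# ---------------------------------------------------------------------------
# replicate experiments


def simulate_fraction_replicates(
    config: SimulationConfig,
    n_replicates: int,
    rng: np.random.Generator,
    analysis_time: float | None = None,
    grid_step: float = 2.0,
    collect_census: bool = False,
) -> tuple[DriftReplicateSet, list[CensusSeries]]:
    """Repeat the timing-only simulation and read descendant fractions.

    Fractions are computed from un-thinned per-ancestor counts at the
    analysis time (default: the configured horizon).  Optionally keeps
    every replicate's census series (for harmonic-mean estimates).
    """
    at = config.t_end if analysis_time is None else analysis_time
    grid = np.arange(0.0, config.t_end + grid_step / 2, grid_step)
    alpha = malthusian_rate(config) if config.age_law == "stationary" else None
    rows = []
    censuses: list[CensusSeries] = []
    for _ in range(n_replicates):
        census = branching_census(config, rng, time_grid=grid, alpha=alpha)
        idx = int(np.searchsorted(census.times, at, side="right") - 1)
        keys = sorted(census.per_ancestor)
        counts = np.array([census.per_ancestor[k][idx] for k in keys])
        rows.append(counts / counts.sum())
        if collect_census:
            censuses.append(census)
    return DriftReplicateSet(np.array(rows), analysis_time=at), censuses


def ar_params_for_targets(
    pp_corr: float,
    sib_corr: float,
    base: BifurcatingARParams,
) -> BifurcatingARParams:
    """Re-parameterise the autoregression to hit target family correlations.

    theta is set to the parent-progeny target; the noise correlation rho
    is solved from the sibling target at the base sigma2; mu and m are
    then adjusted so the equilibrium mean and variance stay at the base
    values.  Raises EstimationError for infeasible pairs (sib < theta^2).
    """
    base_mom = stationary_moments(base)
    theta = pp_corr
    if theta**2 >= 1:
        raise EstimationError("parent-progeny target must satisfy theta^2 < 1")
    a = (sib_corr - theta**2) / (1 - theta**2)
    if a < -1e-12 or a >= 1:
        raise EstimationError(
            f"infeasible correlation pair: sibling {sib_corr} vs theta^2 {theta**2:.3f}"
        )
    a = max(a, 0.0)
    s2 = base.sigma2
    # invert (e^{rho s2}-1)/(e^{s2}-1) = a  =>  rho = ln(1 + a(e^{s2}-1))/s2
    rho = float(np.log1p(a * np.expm1(s2)) / s2)
    mu = 0.5 * np.log(base_mom["variance"] * (1 - theta**2) / (np.exp(s2) * np.expm1(s2)))
    m = base_mom["mean"] - np.exp(mu + s2 / 2) / (1 - theta)
    return BifurcatingARParams(m=float(m), theta=float(theta), mu=float(mu),
                               sigma2=s2, rho=rho)


def correlation_sweep(
    base_config: SimulationConfig,
    pp_corr_grid,
    sib_corr_grid,
    n_replicates: int,
    rng: np.random.Generator,
    analysis_time: float | None = None,
) -> np.ndarray:
    """Effective size K over a grid of family-correlation targets.

    Each grid point re-derives AR parameters holding the marginal
    cycle-time mean and variance fixed, simulates ``n_replicates``
    populations and estimates K from the fraction variance.  Infeasible
    pairs (sibling < theta^2) yield NaN rather than an exception.
    Returns a (len(pp), len(sib)) array.
    """
    pp_grid = np.atleast_1d(np.asarray(pp_corr_grid, dtype=float))
    sib_grid = np.atleast_1d(np.asarray(sib_corr_grid, dtype=float))
    out = np.full((len(pp_grid), len(sib_grid)), np.nan)
    for i, pp in enumerate(pp_grid):
        for j, sib in enumerate(sib_grid):
            try:
                ar_g1 = ar_params_for_targets(pp, sib, base_config.ar_g1)
                ar_sg = ar_params_for_targets(pp, sib, base_config.ar_sg2m)
            except EstimationError:
                continue
            cfg = replace(base_config, ar_g1=ar_g1, ar_sg2m=ar_sg, model_variant="full")
            reps, _ = simulate_fraction_replicates(
                cfg, n_replicates, rng, analysis_time=analysis_time
            )
            out[i, j] = effective_size(reps).k_hat
    return out
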
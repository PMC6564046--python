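"""FUCCI reporter kinetics within one cell cycle.

The Cdt1-linked marker C and Geminin-linked marker G obey

    dC/dt = p_C - d_C C - a (t - T_G1)_+ C
    dG/dt = p_G - d_G G - b (T_G1 - t)_+ G

with constant production rates and phase-dependent degradation: the
Cdt1 marker acquires a linearly growing extra degradation throughout
S/G2/M (slope ``a``), the Geminin marker a linearly vanishing one during
G1 (slope ``b``).  Degradation constants are common to all cells;
production rates vary per cell, either via the heuristic peak/duration
link (p_C = C_G1/T_G1 * vartheta_C, p_G = G_end/T_SG2M * vartheta_G) or
via linear regressions on phase duration and inherited amount with
sibling-correlated noise.

At division each marker amount is split between the progeny by an
independent symmetric beta fraction with coefficient of variation ``cv``
(shape alpha = beta = (cv^-2 - 1)/2); the split conserves mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinKineticsParams",
    "ProductionRegressionParams",
    "DivisionLawParams",
    "Trajectory",
    "simulate_trajectory",
    "heuristic_rates",
    "draw_production_rates",
    "divide_proteins",
    "fit_cell_ode",
    "fit_production_regression",
]

TRAJECTORY_COLUMNS = ["cell_id", "time_h", "cdt1", "geminin"]


@dataclass(frozen=True)
class ProteinKineticsParams:
    """Degradation constants and heuristic factors, common to all cells.

    d_c   background Cdt1-marker degradation (1/h)
    d_g   background Geminin-marker degradation (1/h)
    a     slope of the S/G2/M-specific Cdt1 degradation (1/h^2)
    b     slope of the G1-specific Geminin degradation (1/h^2)
    vartheta_c, vartheta_g
          dimensionless factors linking production rate to peak/duration
    """

    d_c: float = 0.08
    d_g: float = 0.0
    a: float = 0.088
    b: float = 0.124
    vartheta_c: float = 6.0
    vartheta_g: float = 4.0

    def __post_init__(self):
        for name in ("d_c", "d_g", "a", "b", "vartheta_c", "vartheta_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProductionRegressionParams:
    """Linear models for per-cell production rates with sibling-correlated noise.

        p_C = a_g1   + r1_g1 * T_G1     + r2_g1 * C_0   + eps_C
        p_G = a_sg2m + r1_sg2m * T_SG2M + r2_sg2m * G_0 + eps_G

    (eps_C sib1, eps_C sib2) are bivariate normal with sd ``noise_sd_c``
    and correlation ``rho_pc``; analogously for eps_G.  Negative rate
    draws are clipped to zero (rates are physical).
    """

    a_g1: float = 20.0
    r1_g1: float = 1.5
    r2_g1: float = 0.2
    a_sg2m: float = 10.0
    r1_sg2m: float = 2.0
    r2_sg2m: float = 0.05
    noise_sd_c: float = 4.0
    noise_sd_g: float = 4.0
    rho_pc: float = 0.66
    rho_pg: float = 0.54

    def __post_init__(self):
        if not (-1 <= self.rho_pc <= 1 and -1 <= self.rho_pg <= 1):
            raise ValueError("sibling noise correlations must lie in [-1, 1]")
        if self.noise_sd_c < 0 or self.noise_sd_g < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class DivisionLawParams:
    """Symmetric beta split of marker amounts at division.

    ``cv`` is the coefficient of variation of the split fraction; the
    beta shape follows as alpha = beta = (cv^-2 - 1)/2 (mean 0.5).
    """

    cv: float = 0.13

    def __post_init__(self):
        if not 0 < self.cv < 1:
            raise ValueError("cv must lie in (0, 1)")

    @property
    def alpha_beta(self) -> float:
        return (self.cv**-2 - 1) / 2


@dataclass
class Trajectory:
    """Time-stamped marker intensities of one cell (or tracked segment)."""

    time: np.ndarray
    cdt1: np.ndarray
    geminin: np.ndarray
    cell_id: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "time_h": self.time,
                "cdt1": self.cdt1,
                "geminin": self.geminin,
            }
        )


def _rhs(t, c, g, p_c, p_g, kin: ProteinKineticsParams, t_g1: float):
    dc = p_c - kin.d_c * c - kin.a * max(t - t_g1, 0.0) * c
    dg = p_g - kin.d_g * g - kin.b * max(t_g1 - t, 0.0) * g
    return dc, dg


def _rk4_segment(t0, t1, c, g, p_c, p_g, kin, t_g1, dt):
    """Classic fixed-step RK4 over [t0, t1]; returns dense (t, c, g) arrays."""
    n = max(1, int(np.ceil((t1 - t0) / dt)))
    h = (t1 - t0) / n
    ts = np.empty(n + 1)
    cs = np.empty(n + 1)
    gs = np.empty(n + 1)
    ts[0], cs[0], gs[0] = t0, c, g
    for i in range(n):
        t = t0 + i * h
        k1c, k1g = _rhs(t, c, g, p_c, p_g, kin, t_g1)
        k2c, k2g = _rhs(t + h / 2, c + h / 2 * k1c, g + h / 2 * k1g, p_c, p_g, kin, t_g1)
        k3c, k3g = _rhs(t + h / 2, c + h / 2 * k2c, g + h / 2 * k2g, p_c, p_g, kin, t_g1)
        k4c, k4g = _rhs(t + h, c + h * k3c, g + h * k3g, p_c, p_g, kin, t_g1)
        c = c + h / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
        g = g + h / 6 * (k1g + 2 * k2g + 2 * k3g + k4g)
        ts[i + 1], cs[i + 1], gs[i + 1] = t0 + (i + 1) * h, c, g
    return ts, cs, gs


def simulate_trajectory(
    kin: ProteinKineticsParams,
    p_c: float,
    p_g: float,
    t_g1: float,
    t_cycle: float,
    c0: float,
    g0: float,
    dt: float = 0.25,
    dt_int: float = 0.01,
) -> Trajectory:
    """Integrate the marker ODEs over one cycle.

    Fixed-step RK4 with internal step ``dt_int`` (the right-hand side has
    a kink at t = T_G1, so the two phases are integrated as separate
    segments ending/starting exactly at the boundary); output is linearly
    interpolated onto the uniform grid 0 .. t_cycle with spacing ``dt``.
    """
    if not 0 < t_g1 < t_cycle:
        raise ValueError(f"need 0 < t_g1 < t_cycle, got t_g1={t_g1}, t_cycle={t_cycle}")
    if min(p_c, p_g, c0, g0) < 0 or dt <= 0 or dt_int <= 0:
        raise ValueError("rates, initial amounts and steps must be non-negative/positive")
    t1, c1, g1 = _rk4_segment(0.0, t_g1, c0, g0, p_c, p_g, kin, t_g1, dt_int)
    t2, c2, g2 = _rk4_segment(t_g1, t_cycle, c1[-1], g1[-1], p_c, p_g, kin, t_g1, dt_int)
    t_all = np.concatenate([t1, t2[1:]])
    c_all = np.concatenate([c1, c2[1:]])
    g_all = np.concatenate([g1, g2[1:]])
    grid = np.arange(0.0, t_cycle + 1e-9, dt)
    c_out = np.interp(grid, t_all, c_all)
    g_out = np.interp(grid, t_all, g_all)
    return Trajectory(time=grid, cdt1=np.maximum(c_out, 0.0), geminin=np.maximum(g_out, 0.0))


def heuristic_rates(
    c_g1_peak: float,
    t_g1: float,
    g_end: float,
    t_sg2m: float,
    kin: ProteinKineticsParams,
) -> tuple[float, float]:
    """Peak/duration heuristic: p_C = C_G1/T_G1 * vartheta_C, p_G analogous."""
    if t_g1 <= 0 or t_sg2m <= 0:
        raise ValueError("phase durations must be > 0")
    if c_g1_peak < 0 or g_end < 0:
        raise ValueError("peak amounts must be >= 0")
    return c_g1_peak / t_g1 * kin.vartheta_c, g_end / t_sg2m * kin.vartheta_g


def draw_production_rates(
    t_g1_pair,
    c0_pair,
    t_sg2m_pair,
    g0_pair,
    reg: ProductionRegressionParams,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Production rates for a sibling pair with correlated regression noise.

    Returns ``((p_c1, p_g1), (p_c2, p_g2))``.  The noise pairs for p_C
    and for p_G are each exchangeable bivariate normal (correlations
    ``rho_pc`` / ``rho_pg``), independent of one another.  Negative draws
    are clipped to zero.
    """

    def corr_pair(sd, rho):
        z = rng.standard_normal(2)
        e1 = z[0]
        e2 = rho * z[0] + np.sqrt(max(0.0, 1 - rho**2)) * z[1]
        return sd * e1, sd * e2

    ec1, ec2 = corr_pair(reg.noise_sd_c, reg.rho_pc)
    eg1, eg2 = corr_pair(reg.noise_sd_g, reg.rho_pg)
    pc = [
        reg.a_g1 + reg.r1_g1 * t_g1_pair[i] + reg.r2_g1 * c0_pair[i] + e
        for i, e in enumerate((ec1, ec2))
    ]
    pg = [
        reg.a_sg2m + reg.r1_sg2m * t_sg2m_pair[i] + reg.r2_sg2m * g0_pair[i] + e
        for i, e in enumerate((eg1, eg2))
    ]
    pc = [max(0.0, v) for v in pc]
    pg = [max(0.0, v) for v in pg]
    return (pc[0], pg[0]), (pc[1], pg[1])


def divide_proteins(
    c_end: float,
    g_end: float,
    law: DivisionLawParams,
    rng: np.random.Generator,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Split marker amounts between two progeny; mass conserved exactly.

    X_C and X_G are independent Beta(alpha, alpha) fractions; progeny 1
    gets (X_C c_end, X_G g_end) and progeny 2 the complement.
    """
    if c_end < 0 or g_end < 0:
        raise ValueError("amounts must be >= 0")
    al = law.alpha_beta
    x_c = rng.beta(al, al)
    x_g = rng.beta(al, al)

    def split(total, x):
        # complement by subtraction, with a compensation step so the two
        # shares sum to the parent amount exactly in floating point
        a = x * total
        b = total - a
        if a + b != total:
            a = total - b
        return a, b

    c1, c2 = split(c_end, x_c)
    g1, g2 = split(g_end, x_g)
    return (c1, g1), (c2, g2)


def fit_cell_ode(
    trajectory: Trajectory,
    t_g1: float,
    t_cycle: float,
    kin: ProteinKineticsParams,
    max_nfev: int = 200,
) -> dict:
    """Fit per-cell production rates to an observed trajectory.

    Degradation constants are held fixed (common to all cells); only
    (p_C, p_G) are free.  Initialised at the heuristic rates computed
    from the observed Cdt1 level at the G1/S boundary and the final
    Geminin level; minimises the summed squared deviation between the
    ODE solution (started at the observed initial amounts) and the data.

    Returns ``{"p_c", "p_g", "c_g1_peak", "g_end", "cost", "converged"}``
    where the peak/end amounts are evaluated on the fitted solution.
    """
    from scipy.optimize import least_squares

    t = np.asarray(trajectory.time, dtype=float)
    obs = np.stack([trajectory.cdt1, trajectory.geminin])
    c0, g0 = float(trajectory.cdt1[0]), float(trajectory.geminin[0])
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.25

    if np.allclose(obs, 0.0):
        return {"p_c": 0.0, "p_g": 0.0, "c_g1_peak": 0.0, "g_end": 0.0,
                "cost": 0.0, "converged": True}

    i_g1 = int(np.argmin(np.abs(t - t_g1)))
    p_c0, p_g0 = heuristic_rates(
        max(float(trajectory.cdt1[i_g1]), 1e-6), t_g1,
        max(float(trajectory.geminin[-1]), 1e-6), t_cycle - t_g1, kin,
    )

    def solution(p):
        traj = simulate_trajectory(kin, p[0], p[1], t_g1, t_cycle, c0, g0,
                                   dt=dt, dt_int=0.02)
        c = np.interp(t, traj.time, traj.cdt1)
        g = np.interp(t, traj.time, traj.geminin)
        return np.stack([c, g])

    def residuals(p):
        return (solution(p) - obs).ravel()

    res = least_squares(residuals, x0=[p_c0, p_g0], bounds=([0, 0], [np.inf, np.inf]),
                        max_nfev=max_nfev)
    fitted = solution(res.x)
    return {
        "p_c": float(res.x[0]),
        "p_g": float(res.x[1]),
        "c_g1_peak": float(fitted[0].max()),
        "g_end": float(fitted[1, -1]),
        "cost": float(res.cost),
        "converged": bool(res.status > 0),
    }


def fit_production_regression(cells: pd.DataFrame) -> ProductionRegressionParams:
    """Ordinary-least-squares fit of the production-rate regressions.

    ``cells`` needs columns ``t_g1, t_sg2m, c0, g0, p_c, p_g``.  Sibling
    noise correlations are left at their defaults (they are properties of
    paired residuals, not of the marginal OLS fit).
    """
    import statsmodels.api as sm

    xc = sm.add_constant(cells[["t_g1", "c0"]].to_numpy(float))
    fc = sm.OLS(cells["p_c"].to_numpy(float), xc).fit()
    xg = sm.add_constant(cells[["t_sg2m", "g0"]].to_numpy(float))
    fg = sm.OLS(cells["p_g"].to_numpy(float), xg).fit()
    return ProductionRegressionParams(
        a_g1=float(fc.params[0]), r1_g1=float(fc.params[1]), r2_g1=float(fc.params[2]),
        a_sg2m=float(fg.params[0]), r1_sg2m=float(fg.params[1]), r2_sg2m=float(fg.params[2]),
        noise_sd_c=float(np.sqrt(fc.mse_resid)), noise_sd_g=float(np.sqrt(fg.mse_resid)),
    )
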
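"""Population engines: determinism, growth law, homeostasis."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ccdrift.pedigree import census_from_pedigree
from ccdrift.population import (
    LognormalCycleParams,
    SimulationConfig,
    branching_census,
    init_unsynchronized_ancestors,
    malthusian_rate,
    simulate_lineage,
    simulate_population,
)
from ccdrift.synthetic import default_simulation_config


def _uncorr(**kw):
    base = dict(model_variant="uncorrelated", n_ancestors=1, t_end=300.0,
                population_cap=5_000_000)
    base.update(kw)
    return SimulationConfig(**base)


def test_horizon_before_first_division_keeps_census_constant(rng):
    cfg = default_simulation_config(t_end=1e-3, age_law="synchronized", n_ancestors=3)
    res = simulate_population(cfg, rng, census_step=1e-3)
    assert len(res.pedigree) == 3
    assert np.all(res.census.total == 3)


def test_same_seed_gives_identical_pedigrees():
    cfg = default_simulation_config(t_end=60.0)
    a = simulate_population(cfg, np.random.default_rng(5)).pedigree.to_dataframe()
    b = simulate_population(cfg, np.random.default_rng(5)).pedigree.to_dataframe()
    assert a.equals(b)


def test_population_cap_flags_truncation(rng):
    cfg = default_simulation_config(t_end=200.0, population_cap=30)
    res = simulate_population(cfg, rng)
    assert res.truncated
    assert len(res.pedigree) <= 30 + 1


def test_census_growth_matches_euler_lotka_rate(rng):
    """Log-census slope ~ Malthusian rate of the lognormal cycle law."""
    cfg = _uncorr(cycle=LognormalCycleParams(20.4, 0.30), n_ancestors=10)
    alpha = malthusian_rate(cfg)
    census = branching_census(cfg, rng, alpha=alpha)
    late = census.times >= 100.0  # discard the transient
    slope = np.polyfit(census.times[late], np.log(census.total[late]), 1)[0]
    assert slope == pytest.approx(alpha, rel=0.05)
    # slope is stable across disjoint late windows
    w1 = (census.times >= 100) & (census.times < 200)
    w2 = census.times >= 200
    s1 = np.polyfit(census.times[w1], np.log(census.total[w1]), 1)[0]
    s2 = np.polyfit(census.times[w2], np.log(census.total[w2]), 1)[0]
    assert s1 == pytest.approx(s2, rel=0.1)


def test_event_engine_agrees_with_vectorised_engine():
    """Same variant, same horizon: census growth statistically equivalent."""
    cfg = _uncorr(t_end=120.0, n_ancestors=5, age_law="synchronized")
    finals_ev, finals_vec = [], []
    for seed in range(30):
        res = simulate_population(cfg, np.random.default_rng(seed), census_step=10.0)
        finals_ev.append(res.census.total[-1])
        c = branching_census(cfg, np.random.default_rng(1000 + seed))
        finals_vec.append(c.total[-1])
    p = stats.mannwhitneyu(finals_ev, finals_vec).pvalue
    assert p > 0.01
    assert np.mean(finals_vec) == pytest.approx(np.mean(finals_ev), rel=0.25)


def test_lineage_iid_at_zero_theta(rng):
    """theta = 0 in both phases: generations are i.i.d. in cycle time."""
    from ccdrift.bifurcating import BifurcatingARParams

    cfg = default_simulation_config(
        ar_g1=BifurcatingARParams.from_target_mean(8.6, 0.0, 1.8, 0.27, rho=0.5),
        ar_sg2m=BifurcatingARParams.from_target_mean(11.8, 0.0, 1.8, 0.31, rho=0.62),
    )
    line = simulate_lineage(cfg, 400, rng)
    tc = np.array([c.t_cycle for c in line])
    lag1 = np.corrcoef(tc[:-1], tc[1:])[0, 1]
    assert abs(lag1) < 2.5 / np.sqrt(len(tc))


def test_lineage_autocorrelation_decays_geometrically(rng):
    """lag-k autocorrelation of phase durations ~ theta^k."""
    cfg = default_simulation_config()
    line = simulate_lineage(cfg, 3000, rng)
    sg = np.array([c.t_sg2m for c in line])
    theta = cfg.ar_sg2m.theta
    for k in (1, 2):
        r = np.corrcoef(sg[:-k], sg[k:])[0, 1]
        assert r == pytest.approx(theta**k, abs=0.06)


def test_lineage_forgets_ancestor(rng):
    """Running median of T_C converges to the stationary median regardless
    of an extreme ancestor; long-run median uncorrelated with the start."""
    from ccdrift.bifurcating import stationary_moments

    cfg = default_simulation_config()
    med_short, med_long = [], []
    starts = []
    for rep in range(40):
        frac = 13.6 / 20.4 if rep % 2 == 0 else 61.3 / 20.4
        anc = {"t_g1": 8.6 * frac, "t_sg2m": 11.8 * frac}
        line = simulate_lineage(cfg, 120, np.random.default_rng(rep), ancestor=anc)
        tc = np.array([c.t_cycle for c in line])
        starts.append(tc[0])
        med_long.append(np.median(tc[40:]))
    r = np.corrcoef(starts, med_long)[0, 1]
    assert abs(r) < 0.35  # cf. the near-zero association after many generations
    exp_mean = (stationary_moments(cfg.ar_g1)["mean"]
                + stationary_moments(cfg.ar_sg2m)["mean"])
    assert np.mean(med_long) == pytest.approx(exp_mean, rel=0.1)


def test_division_asymmetry_does_not_affect_timing():
    """Partitioning noise does not feed back into cycle-time statistics:
    mean and CV of T_C are unchanged across cv in [0.05, 0.3]."""
    from ccdrift.proteins import DivisionLawParams

    stats_by_cv = {}
    for cv in (0.05, 0.13, 0.30):
        cfg = default_simulation_config(
            t_end=72.0, division=DivisionLawParams(cv=cv))
        tc = []
        for seed in range(6):
            ped = simulate_population(cfg, np.random.default_rng(seed)).pedigree
            tc.extend(c.t_cycle for c in ped.divided())
        tc = np.array(tc)
        stats_by_cv[cv] = (tc.mean(), tc.std() / tc.mean())
    means = [v[0] for v in stats_by_cv.values()]
    cvs = [v[1] for v in stats_by_cv.values()]
    assert max(means) - min(means) < 0.05 * np.mean(means)
    assert max(cvs) - min(cvs) < 0.12 * np.mean(cvs)


def test_unsynchronized_ages_uniform_given_cycle(rng):
    cfg = _uncorr(n_ancestors=20_000, age_law="uniform")
    anc = init_unsynchronized_ancestors(cfg, rng)
    rel_age = np.array([a["age"] / a["t_cycle"] for a in anc])
    assert np.all(np.array([a["residual"] for a in anc]) > 0)
    assert stats.kstest(rel_age, "uniform").pvalue > 0.01


def test_synchronized_ages_are_zero(rng):
    cfg = _uncorr(n_ancestors=50, age_law="synchronized")
    anc = init_unsynchronized_ancestors(cfg, rng)
    assert all(a["age"] == 0.0 for a in anc)
    assert all(a["residual"] == a["t_cycle"] for a in anc)


def test_stationary_age_law_biases_toward_young(rng):
    """Exponential-tilt init: mean relative age < 0.5 (young-cell excess)."""
    cfg = _uncorr(n_ancestors=20_000, age_law="stationary")
    anc = init_unsynchronized_ancestors(cfg, rng)
    rel_age = np.array([a["age"] / a["t_cycle"] for a in anc])
    assert rel_age.mean() < 0.48


def test_homeostasis_across_extreme_ancestors():
    """Cycle-time distribution at 300 h forgets a 13.6 h vs 61.3 h ancestor."""
    cfg = default_simulation_config(t_end=300.0, population_cap=5_000_000)
    pvals = []
    for rep in range(5):
        samples = {}
        for label, frac in [("fast", 13.6 / 20.4), ("slow", 61.3 / 20.4)]:
            rng = np.random.default_rng(10 * rep + (0 if label == "fast" else 1))
            tc = _terminal_cycle_times(cfg, frac, rng)
            samples[label] = tc
        pvals.append(stats.ks_2samp(samples["fast"], samples["slow"]).pvalue)
    # across replicates the KS test should typically NOT reject
    assert np.median(pvals) > 0.05


def _terminal_cycle_times(cfg, ancestor_scale, rng, n_sample=400):
    """Timing-only run from one scaled ancestor; cycle times of cells
    alive in the last 20 h."""
    from ccdrift.population import _inherit_vec

    g1 = np.array([8.6 * ancestor_scale])
    sg = np.array([11.8 * ancestor_scale])
    birth = np.array([0.0])
    div = birth + g1 + sg
    out = []
    while True:
        live = div < cfg.t_end
        if not live.any():
            keep = div >= cfg.t_end
            out.append((g1 + sg)[keep])
            break
        keep = div >= cfg.t_end
        out.append((g1 + sg)[keep])
        nb = np.repeat(div[live], 2)
        g1 = _inherit_vec(g1[live], cfg.ar_g1, rng)
        sg = _inherit_vec(sg[live], cfg.ar_sg2m, rng)
        birth, div = nb, nb + g1 + sg
    tc = np.concatenate(out)
    if len(tc) > n_sample:
        tc = rng.choice(tc, size=n_sample, replace=False)
    return tc


def test_population_size_anticorrelated_with_ancestor_cycle():
    """Sign test: longer ancestor cycle => smaller population at 200 h."""
    cfg = default_simulation_config(t_end=200.0, population_cap=5_000_000)
    rng = np.random.default_rng(77)
    sizes, cycles = [], []
    for rep in range(24):
        scale = rng.uniform(0.6, 2.5)
        c = _terminal_population_size(cfg, scale, np.random.default_rng(rep))
        cycles.append(scale * 20.4)
        sizes.append(c)
    r = stats.spearmanr(cycles, sizes).statistic
    assert r < -0.5


def _terminal_population_size(cfg, ancestor_scale, rng):
    from ccdrift.population import _inherit_vec

    g1 = np.array([8.6 * ancestor_scale])
    sg = np.array([11.8 * ancestor_scale])
    div = g1 + sg
    n_alive = 0
    while True:
        live = div < cfg.t_end
        n_alive += int((~live).sum())
        if not live.any():
            return n_alive
        nb = np.repeat(div[live], 2)
        g1 = _inherit_vec(g1[live], cfg.ar_g1, rng)
        sg = _inherit_vec(sg[live], cfg.ar_sg2m, rng)
        div = nb + g1 + sg
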
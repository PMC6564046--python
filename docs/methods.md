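# Methods

This note documents the models implemented in `ccdrift`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
data used by the test suite does and does not establish.

## Phase-duration inheritance

Each cell-cycle phase (G1 and S/G2/M, treated as independent processes)
follows a first-order autoregression on the binary lineage tree:

    T_i = m + θ (T_parent − m) + W_i,   i = 1, 2,

with one exchangeable bivariate lognormal noise pair per division:
`(W_1, W_2) = (e^{X_1}, e^{X_2})` where `(X_1, X_2)` is bivariate
normal with common mean `μ`, common variance `σ²` and correlation `ρ`.
Lognormal noise keeps durations positive and right-skewed, matching
observed duration histograms; a Gaussian-noise variant is deliberately
not provided.

Equilibrium moments (for `θ² < 1`) are closed-form (see README). One
derivation note: the cousin–cousin correlation is
`corr(sib) · θ²`, not `corr(sib) · θ` — cousins are connected through
the chain cousin → parent → parent's sibling → cousin, so their
covariance is `θ² Cov(parents)`; every generation of separation costs a
factor `θ`. This is confirmed by simulation in the test suite
(2 × 10⁵ families reproduce the `θ²` form to three decimals).

### Estimation

Method of moments: `θ̂` is the parent–progeny correlation; the sibling
correlation, after removing the inherited part, gives
`Â = (ρ̂_sib − θ̂²)/(1 − θ̂²)`, which equals the lognormal pair
correlation `(e^{ρσ²}−1)/(e^{σ²}−1)`. At an assumed `ρ > Â` the
transcendental equation `x^ρ − 1 = Â(x − 1)` has a single root
`x₀ > 1`, found by geometric bracket growth (cap 10¹²) and bisection to
relative width 10⁻¹³; `σ̂² = ln x₀`, then `μ̂` and `m̂` follow by exact
inversion of the mean/variance relations, so refitting the implied
equilibrium moments reproduces the inputs to 10⁻⁹ (tested).

Identifiability caveats, verified empirically and asserted in tests:

* `ρ` is not identified by first/second moments. `fit(rho_grid=...)`
  profiles it by the Kolmogorov–Smirnov distance between observed
  durations and a 10⁵-draw sample of the implied equilibrium
  distribution (the criterion is this package's choice; the marginal
  equilibrium law depends on `ρ` only through the fitted `σ², μ, m`).
* As `ρ → Â⁺` the root `x₀ → 1` (σ² → 0); as `ρ → 1⁻` it runs away to
  infinity — the solver reports non-convergence rather than returning a
  spurious root. Near the boundary, sampling noise in `Â` (sd ≈ 0.03 at
  10³ cells) translates into order-of-magnitude spread in `σ̂²`; a
  ~10³-cell pedigree supports `θ̂` to ±0.05 but `σ̂²` only to ~±50%.
* Correlation estimates use the symmetrized-pair convention for
  exchangeable pairs (each sibling/cousin pair enters in both orders);
  parent–progeny pairs are ordered. Standard errors via Monte Carlo
  cross-validation resampling (configurable iteration count).

Equilibrium sampling uses the exact moving-average representation
`T = m + Σ_k θ^k W_k`, truncated when `θ^k < 10⁻¹²`.

## Reporter kinetics

Within a cycle with known G1 length `T_G1` and cycle length `T_C`:

    dC/dt = p_C − d_C C − a (t − T_G1)₊ C
    dG/dt = p_G − d_G G − b (T_G1 − t)₊ G

Degradation constants are common to all cells: `d_C = 0.08 h⁻¹`,
`d_G = 0` (the Geminin reporter has no background decay; the `b`-term
alone clears it during G1), `a = 0.088 h⁻²`, `b = 0.124 h⁻²`,
heuristic factors `ϑ_C = 6`, `ϑ_G = 4`. Production rates vary per cell.

Integration is classic fixed-step RK4 (default internal step 0.01 h),
split into the two smooth regimes at `t = T_G1` so the kink never sits
inside a step; output is linearly resampled onto the requested grid.
Step-halving confirms 4th-order convergence at integration nodes; the
independent oracle in the tests is the integrating-factor solution
evaluated by adaptive quadrature (agreement ≤ 10⁻⁶ relative).

A structural consequence of these constants: the Cdt1 peak lags the
biochemical G1/S switch by `Δ ≈ (p_C/C(T_G1) − d_C)/a ≈ 0.9 h`, because
C is still rising when the S-phase degradation starts. The operational
definition of the transition — the Cdt1 peak — therefore differs from
the ODE switch time by a nearly constant offset. The synthetic ground
truth records both times, and detection accuracy is scored against the
operational one, which is also what real analyses report.

Per-cell rates: either the peak/duration heuristic
(`p_C = C_G1/T_G1 · ϑ_C`, `p_G = G_end/T_SG2M · ϑ_G` — a linear
interpolation of exponential arcs, used to initialise fitting) or
linear regressions on phase duration and inherited amount with
sibling-correlated bivariate-normal errors (correlations 0.66 for
`p_C`, 0.54 for `p_G`). Negative draws are clipped to zero. Regression
coefficients default to the synthetic generator's ground truth and can
be re-estimated from per-cell fitted rates by OLS (statsmodels).
Per-cell ODE fitting holds the degradation constants fixed and
optimises `(p_C, p_G)` by bounded least squares from the heuristic
start; a non-convergent fit is flagged, not silently returned.

At division both marker amounts are split by independent symmetric beta
fractions. The coefficient of variation is the primitive
(`cv = 0.13` default) and the shape follows as
`α = β = (cv⁻² − 1)/2 ≈ 29.09` (the commonly quoted 29.3 appears to be
a rounding of the same formula). The compensated subtraction in the
split makes conservation exact in floating point, and a regression test
confirms that varying `cv` over [0.05, 0.3] leaves the long-run timing
statistics unchanged — partitioning noise does not feed back into the
timing model.

## Endpoint detection

For a tracked trace sampled every 0.25 h: (1) estimate the relative
noise level as the median relative residual of a first-pass
local-quadratic fit, and set the smoothing window to
`clamp(8 σ̂_rel, 1 h, 4 h)` (default fixed 2 h ≈ 9 points); (2) smooth
both channels with local weighted least squares, degree-2 polynomial
(Savitzky–Golay — exact on quadratics); (3) differentiate the Geminin
channel (central differences); (4) divisions are local minima of the
derivative deeper than 2× the median absolute derivative, at least 5 h
apart (both knobs configurable); (5) the G1→S transition in each
division interval is the argmax of smoothed Cdt1, rejected if flat or
on the interval boundary. Quality-failure reasons are enumerated:
`flat-signal`, `high-noise` (σ̂_rel > 0.5), `peak at boundary`,
`missing-division`. All thresholds are package choices; no published
numeric values exist for them.

A division whose drop lies within ~half a smoothing window of the film
end is undetectable in principle; the synthetic ground truth therefore
counts a cycle as complete (observable) only if the closing division
occurs ≥ 1 h before the film ends.

## Population engines

The event-driven engine (priority queue on division times, ties broken
by cell id) carries full per-cell state and returns a pedigree plus
census; it is the reference implementation and is used for film-scale
synthesis (10²–10³ cells). The generation-sweep engine propagates only
(birth, division, phase durations) through numpy arrays and computes
census counts by sorted-search, making 10⁵–10⁶-cell drift experiments
take seconds; the two are cross-validated on identical configurations.

Variants: `full` (bifurcating autoregression of both phases) and
`uncorrelated` (i.i.d. lognormal **total** cycle times, split by a
fixed G1 share of 0.42 for protein bookkeeping only; the source
material is ambiguous between total-cycle and per-phase lognormal
draws, and the total-cycle reading is implemented).

Ancestors default to unsynchronized: each draws a full cycle and an age
uniform on `[0, T_C)`. A `stationary` law (cycle tilted by
`1 − e^{−αT}`, age truncated-exponential — the age structure of an
exponentially growing steady state) and a `synchronized` law are
options; the drift results are mildly sensitive to this choice (the
stationary law raises fraction variance by ~25% at N = 3).

The Malthusian rate `α` solves the binary-fission renewal equation
`2 E[e^{−αT}] = 1` — by 96-node Gauss–Hermite quadrature for the
lognormal law, by 2×10⁵-draw Monte Carlo for the autoregressive
stationary law — and is used for initialisation and for the analytic
census benchmark `K = N₀ α Δt` behind the harmonic-mean law.

## Drift analysis

From M replicate simulations started from N ancestors, the per-ancestor
descendant fractions at the analysis time (default 300 h; the fractions
are empirically stable from ~25 h on at these growth rates, and the
drift literature's "determined after 200 h" window is comfortably
past saturation) form an (M, N) matrix. The effective size is
`K̂ = (N−1)/(N² V̂)` with `V̂` the across-replicate fraction variance
centred on per-ancestor means (unbiased, M/(M−1) corrected). Reported
alongside: the raw statistics `S_r²` (centred on 1/N) and `S_c²`
(centred per ancestor), the moment covariance, and the closed-form
expectations `Var(Y_i) = (N−1)N⁻²K⁻¹`, `ρ = −1/(N−1)`.

A caveat the implementation surfaces rather than hides: because every
fraction row sums to one, `S_c² ≈ S_r²` up to O(1/M) and the
moment-based covariance sits near zero — the negative cross-correlation
is absorbed by the centring and is *not* recoverable from these
statistics (the direct column-pair correlation across replicates does
recover `−1/(N−1)` on multinomial fixtures). `K̂` is unaffected; it
uses the variance only.

Harmonic-mean K is computed two ways — trapezoid integration of
`1/N(τ)` on the census grid, and the exponential-growth closed form
`N₀N_T/(N_T−N₀)·ln(N_T/N₀)` — which agree to a few percent for clean
exponential growth and exactly equal N for constant census.

The binomial comparison pools all M·N scaled fractions `Y·K̂` against
an equal-size fresh `Binom(round(K̂), 1/N)` sample and reports both
CDFs and a two-sample Wilcoxon (Mann–Whitney) p-value; pooling is this
package's choice and is calibrated under the null in the tests.

The correlation sweep re-derives AR parameters for each
(parent–progeny, sibling) target pair holding the equilibrium mean and
variance fixed: `θ` = parent–progeny target, `ρ` solved from the
sibling target at the base `σ²`, `μ, m` re-adjusted. Pairs with
sibling < θ² are infeasible and yielded as NaN. K is estimated per grid
point from replicate fraction variances; K̂ is largest at (0, 0), where
it matches the harmonic-mean law within sampling error, and decreases
along both correlation axes.

## Synthetic data

The generator emulates a 72 h film at 15-minute sampling: lineages from
unsynchronized ancestors, cell-centric traces covering each cell's
cycle plus ~2 h of parent/progeny context (so both flanking division
drops are inside the trace), multiplicative lognormal measurement noise
(default 5% relative sd, optional additive floor), and a sidecar JSON
with the seed, all generating parameters and per-cell true endpoints.

Default timing parameters were fixed once from published 15%-serum
summary statistics — mean cycle 20.4 h, CV 0.30, G1 ≈ 42% of the cycle,
S/G2/M more heritable than G1, sibling correlations well above
parent–progeny — as moment targets (G1: mean 8.6 h, var 16 h²,
ρ_sib 0.50, θ 0.25, ρ 0.50; S/G2/M: mean 11.8 h, var 21.4 h², ρ_sib
0.65, θ 0.40, ρ 0.62) and are derived through the moment inversion at
import time, not hard-coded. The noise-correlation choices keep the
lognormal noise CV near 0.5–0.6; larger assumed ρ would force
implausibly heavy-tailed noise for the same sibling correlation.
Production-regression defaults were chosen for stable, FUCCI-shaped
trajectories under the fixed degradation constants (Cdt1 peaking near
G1/S, Geminin peaking at division, protein levels stationary across
generations).

What passing tests on these data do **not** show: robustness to
tracking errors, segmentation artefacts, uneven sampling, photobleaching
trends, dormant (G0) cells, or cell death — none of which the generator
emulates. Conclusions about real recordings require the corresponding
raw data; the package ships an import-only spreadsheet reader for that
purpose.

## Problem sizes

The test suite and the reproduction script run simulations at sizes
chosen as a deliberate accuracy/turnaround trade-off: drift experiments
use 300–1500 replicates (K̂ has relative sd `√(2/M)` ≈ 4–8%),
closed-loop recovery uses 20 films of 15 lineages, harmonic-mean checks
use 20–24 replicates of 25-ancestor populations (~10⁶ cells each, via
the generation-sweep engine). Larger runs change none of the
conclusions, only the Monte Carlo error bars.
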
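# ccdrift

Heritable cell-cycle timing, FUCCI reporter dynamics and epigenetic
drift in proliferating cell pedigrees.

## The problem

Time-lapse imaging of FUCCI-labelled mammalian cells (e.g. NIH 3T3
fibroblasts) yields pedigrees annotated with each cell's G1 and S/G2/M
residence times and the intensities of its Cdt1- and Geminin-linked
reporters. Two questions drive this package:

1. **How heritable is cell-cycle timing?** Phase durations are
   correlated between relatives — strongly between siblings, more
   weakly between parent and progeny — and this structure is captured
   by a *bifurcating autoregression* on the lineage tree: both progeny
   of a parent with phase duration `T` receive

   ```
   T_i = m + θ (T − m) + W_i ,   i = 1, 2
   ```

   where `(W_1, W_2)` is an exchangeable bivariate *lognormal* pair
   (exponentiated bivariate normal with mean `μ`, variance `σ²`,
   correlation `ρ`). At equilibrium

   ```
   E(T)   = m + e^{μ+σ²/2}/(1−θ)
   Var(T) = e^{2μ} e^{σ²}(e^{σ²}−1)/(1−θ²)
   corr(siblings)        = θ² + (1−θ²)(e^{ρσ²}−1)/(e^{σ²}−1)
   corr(parent, progeny) = θ
   ```

   and the package inverts these relations (method of moments,
   including the transcendental solve `x^ρ − 1 = Â(x − 1)` for
   `x = e^{σ²}`) to estimate `(m, θ, μ, σ²)` from pedigree data at an
   assumed or profiled `ρ`.

2. **What does heritable timing do to a growing population?** Lineages
   founded by fast-cycling cells overrepresent their descendants — a
   drift-like effect. Comparing per-ancestor descendant fractions at a
   fixed time against a Wright–Fisher population of effective size `K`
   (via `Var(Y_i) = (N−1) N⁻² K⁻¹`) quantifies it; family correlations
   push `K` well below the classical harmonic-mean-census benchmark
   `K = N₀N_T/(N_T−N₀) · ln(N_T/N₀)`.

Per-cell reporter kinetics are modelled by a two-regime linear ODE
(constant production, phase-dependent degradation), protein content is
split at division by a symmetric Beta(α, α) fraction with
`α = (cv⁻² − 1)/2`, and division/G1→S events are recovered from noisy
traces by local-quadratic smoothing, numerical differentiation of the
Geminin channel, and Cdt1 peak detection.

A first-class synthetic-data module generates pedigrees and noisy
trajectory tables with known ground truth, so the entire pipeline is
testable without any download.

## Worked example

```python
import numpy as np
from ccdrift import (BifurcatingAutoregression, SyntheticConfig,
                     generate_experiment)

gt = generate_experiment(SyntheticConfig(n_lineages=25, seed=7))
model = BifurcatingAutoregression(gt.pedigree, phase="sg2m")
print(model.fit(rho=0.7).summary())
```

```
Bifurcating autoregression - method of moments
======================================================
phase: sg2m    cells: 575  sib pairs: 275  pp pairs: 550
------------------------------------------------------
                      estimate
m (h)                   5.7484
theta                   0.3214
mu (log h)              0.9608
sigma2                  0.8420
rho (assumed)           0.7000
A_hat                   0.6078
x0                      2.3210
------------------------------------------------------
moment                  sample      fitted
mean (h)               11.6169     11.6169
variance (h^2)         23.3618     23.3618
rho sibling             0.6483      0.6483
rho parent              0.3214      0.3214
rho cousin              0.0399      0.0670
```

The fitted `θ ≈ 0.32` is the parent–progeny correlation of S/G2/M
durations (generator truth: 0.40; a 25-lineage film is modest), and the
moment inversion reproduces the sample mean, variance and sibling
correlation exactly by construction. `ρ` is not identified by these
moments — `σ²` trades off against the assumed `ρ` (fit with
`rho_grid=...` to profile it by distribution fit). The cousin row is
not used in fitting: the model predicts `corr(cousins) = corr(sib)·θ²`
(two inheritance steps), and the sample value is its noisy counterpart.

Drift side, from a shell:

```sh
ccdrift drift --ancestors 10 --reps 300 --at 300 --variant uncorrelated \
    --seed 1 --out drift.json
```

reports `k_hat ≈ 112.7` against `harmonic_mean_k ≈ 111.6` for
independent lognormal cycle times (mean 20.4 h, CV 0.30): without
family correlations the fraction-variance estimate sits essentially on
the harmonic-mean law. With correlations switched on
(`--variant full`), `k_hat` drops far below it. Other subcommands: `synth`, `simulate`, `detect`, `estimate`,
`drift-sweep`, `validate`.

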
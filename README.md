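# salipm

Size-structured demographic analysis for terrestrial salamanders
(*Plethodon cinereus*-type life histories): joint Bayesian
capture–mark–recapture estimation of size-dependent survival, growth,
recapture, and fecundity; an integral projection model (IPM) built from the
posterior; and manual-perturbation elasticity analysis of the asymptotic
population growth rate.

The package is aimed at population ecologists who have individual
capture-history data (sizes, detections, egg counts over repeated occasions)
and want population-level conclusions — the growth rate λ, the stable size
distribution, and the sensitivity of λ to selection on body size — with full
posterior uncertainty carried through every stage. A built-in
individual-based simulator of the two-season, three-site cover-board design
makes every stage testable without field data.

## The model

Vital rates are functions of snout-to-vent length *x* (mm):

- growth (Fabens / von Bertalanffy increment): x′ ~ N(e^{−K}x + L(1−e^{−K}), a + bx)
- monthly survival (log-log hazard link): S_m(x) = exp(−exp(e + fx)), interval
  survival S_m^Δt on a half-month grid, annual survival S_m^12
- recapture: logit p(x) = g + hx
- eggs per mature female (x ≥ 36 mm): E(x) = c + dx, normal likelihood

with additive site and season offsets. All coefficients are estimated
jointly from one capture table by MCMC (CJS likelihood with latent alive
states marginalized analytically, vague N(0, 10²) priors, Gelman–Rubin
R < 1.01 convergence rule). The annual female-only prebreeding IPM

  n(t+1, x′) = ∫ [ S(x′) G(x′|x) + I(x′) S₀ H ½ E(x) 1[x ≥ 36] ] n(t, x) dx

is discretized on 100 cells over 0–65 mm (H = 0.9 hatching, S₀ = 0.574
first-year recruitment, recruits at N(25, 2) mm). λ and the stable size
distribution are the dominant eigenpair; elasticities are computed by
rebuilding the kernel after ±1% perturbations of K, L, or f
(E_λ = 100(λ_p − λ₀)/λ₀). See `docs/methods.md` for the full account.

## Worked example

```python
from salipm import (SimulationTruth, simulate_population,
                    CaptureRecaptureModel, MCMCConfig,
                    build_kernel, lambda_and_stable,
                    season_average_elasticity, posterior_mean_params)

params = posterior_mean_params()          # published posterior means

# population growth rate of the two seasonal environments
for season in (1, 2):
    lam, stable = lambda_and_stable(build_kernel(params, season=season))
    print(f"season {season}: lambda = {lam:.3f}")

# elasticity of lambda to a 1% decrease in the survival slope f
print(season_average_elasticity(params, "f", -0.01))

# simulate the study design and re-estimate everything from scratch
data = simulate_population(SimulationTruth(seed=1))
post = CaptureRecaptureModel(data).fit(MCMCConfig(seed=1))
print(post.summary().loc[["K", "L", "e", "f"]].round(3))
```

prints

```
season 1: lambda = 0.783
season 2: lambda = 0.714
{'season1': -1.2575997364722427, 'season2': -2.789314726707999, 'average': -2.023457231590121}
     mean     sd    2.5%   97.5%   rhat
K   0.503  0.024   0.455   0.549  1.009
L  43.555  0.230  43.099  43.989  1.016
e  -0.788  0.308  -1.372  -0.186  1.008
f  -0.048  0.008  -0.064  -0.033  1.007
```

A λ below 1 means the population declines at its stable size structure;
season-2 vital rates (lower small-size survival) give the lower λ. The
elasticity output says a 1% weakening of the size–survival slope costs
about 2% of λ on average across seasons (2.8% under season-2 rates), and
the posterior summary shows the sampler recovering the growth and survival
coefficients that generated the data, with their 95% credible intervals.

A command-line pipeline wraps the same machinery:

```bash
salipm simulate --seed 1 --out runs/sim
salipm fit --data runs/sim/capture_histories.csv --seed 1 --out runs/fit
salipm ipm --draws runs/fit/posterior_draws.csv --out runs/ipm
salipm elasticity --draws runs/fit/posterior_draws.csv --out runs/ela
salipm run-all --seed 1 --out runs/all     # everything, one results.json
```

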
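# weibullmeans

Interval estimation for the **common mean of several independent Weibull
distributions**, with a worked application to monthly wind-speed records
from three districts of Surat Thani province, Thailand.

Wind speeds (and lifetimes, failure times, claim sizes, …) at a single
site are well described by a two-parameter Weibull distribution with
scale `c` and shape `k`,

```
f(x; c, k) = (k/c) (x/c)^(k-1) exp(-(x/c)^k),   x > 0,
```

whose mean is `μ = c Γ(1 + 1/k)`. When `p` sites are assumed to share one
mean, the natural point estimate pools the per-site ML estimates
`μ̂_i = ĉ_i Γ(1 + 1/k̂_i)` with inverse-variance weights,

```
μ̂ = Σ_i (μ̂_i / v̂ar(μ̂_i)) / Σ_i (1 / v̂ar(μ̂_i)),
```

where `v̂ar(μ̂_i)` comes from the delta method with the observed
information of the Weibull fit. The package provides four interval
estimators for `μ`:

| method | idea | stochastic? |
|---|---|---|
| `gci` | generalized confidence interval from pivotal quantities of `(ĉ, k̂)` simulated via unit-Weibull star samples | yes (seeded) |
| `mover` | adjusted MOVER: per-group log-scale Wald limits recombined around the pooled estimate | no |
| `bayes-et` | equitailed credible interval from a Gibbs / random-walk-Metropolis sampler under diffuse gamma priors | yes (seeded) |
| `bayes-hpd` | highest-posterior-density interval from the same posterior draws | yes (seeded) |

plus a Monte-Carlo engine that estimates coverage probability and
expected length of all four methods under configurable scenarios, and an
AIC screen comparing the Weibull fit against gamma, lognormal, normal,
exponential and Cauchy alternatives.

## Worked example

The bundled dataset (`--fixture surat_thani`) holds 50 monthly wind
speeds (m/s, 2010–2019) for each of Khiri Rat Nikhom, Koh Samui and
Kanchanadit. Fitting the three groups:

```sh
weibullmeans fit --fixture surat_thani
```

```json
[
  {"group": "khiri_rat_nikhom", "n": 50, "c_hat": 0.906366, "k_hat": 4.76694,
   "mu_hat": 0.829898, "var_mu": 0.000793382, "loglik": 10.7124},
  {"group": "koh_samui",        "n": 50, "c_hat": 1.18043,  "k_hat": 3.63491,
   "mu_hat": 1.06425,  "var_mu": 0.00210368,  "loglik": -15.1048},
  {"group": "kanchanadit",      "n": 50, "c_hat": 0.756365, "k_hat": 2.21777,
   "mu_hat": 0.669877, "var_mu": 0.00203273,  "loglik": -12.3979},
  {"group": "__pooled__", "n": 150, "mu_hat": 0.844566}
]
```

Khiri Rat Nikhom's large shape (`k̂ ≈ 4.8`) marks a narrow, regular wind
regime; Kanchanadit (`k̂ ≈ 2.2`) is the most variable and has the lowest
mean. The pooled common mean is 0.8446 m/s, pulled toward Khiri Rat
Nikhom's precise estimate by the inverse-variance weights. A 95%
generalized confidence interval for the common mean:

```sh
weibullmeans ci --method gci --seed 1 --fixture surat_thani
```

```json
[{"method": "gci", "level": 0.95, "seed": 1, "m": 2500,
  "lower": 0.794065, "upper": 0.896083, "length": 0.102018}]
```

so the common monthly mean wind speed is estimated between about 0.79
and 0.90 m/s. The Bayesian intervals (`--method bayes-et` /
`bayes-hpd`) land in the same place with the HPD interval never longer
than the equitailed one; the MOVER interval (`--method mover`) is
narrower but, as the simulation engine shows, pays for it with coverage
below the nominal level at small samples:

```sh
weibullmeans simulate --p 2 --n 10,10 --mu 1 --k 2 --reps 1000 \
    --methods gci,mover --seed 1
```

Library use mirrors the CLI:

```python
import weibullmeans as wm

samples = wm.load_surat_thani()
interval = wm.gci_interval(samples, wm.GciConfig(m=2500, seed=1))
et, hpd, chains, pooled = wm.bayes_intervals(samples, config=wm.McmcConfig(seed=1))
```

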
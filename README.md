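# terrapop

Survival estimation and population-decline simulation for an adult-only
mark-recapture study of diamondback terrapins (*Malaclemys terrapin*) in a
mangrove creek system, built for wildlife demographers who need the whole
chain — encounter histories → survival estimates → stage-structured
projection → candidate-mechanism scenarios — as tested, reusable code.

## What it computes

**Cormack–Jolly–Seber (CJS) survival.** From per-animal 0/1 encounter
histories over annual occasions, `terrapop.cjs_model` maximizes the
conditional-on-first-capture likelihood with the χ recursion
χ_K = 1, χ_t = (1 − φ̃_t) + φ̃_t (1 − p_{t+1}) χ_{t+1},
where φ̃_t = φ_t^Δt handles multi-year gaps between occasions. Apparent
survival φ can vary by sex, year (factor or trend) and hurricane interval;
detection p by sex and annual effort, all on the logit scale. Confidence
intervals come from the delta method on the observed information, and
confounded parameters (the terminal φ·p product of time-varying models) are
flagged inestimable rather than reported.

**Female-only Leslie matrix.** `terrapop.leslie_model` builds the 5-class
(ages 0–3, 4+) projection matrix with fertility
F = (clutch size × clutches/season × clutch survival × egg survival ×
proportion female) × S_j^{9/12} — 0.7096 female hatchlings per breeding
female at the default rates, before the nine-month juvenile discount — and
the pooled-adult retention probability
P_a = S_a (1 − (S_a/λ)^{T−1}) / (1 − (S_a/λ)^T), T = l − m + 1
(fixed stage duration, maturity m = 4, longevity l = 40, λ = 1). The
dominant eigenvalue is the asymptotic growth rate; its right eigenvector,
the stable age distribution. `solve_Sj` calibrates juvenile survival so
projected λ matches a realized value.

**Stochastic projection.** `terrapop.projection_sim` propagates integer
age-class counts with binomial survival and Poisson recruitment
(n0(t) ~ Poisson(n4+(t) × F)), replicated from independent substreams of a
master seed, reporting per-year means and 2.5/97.5% quantiles of adult
females.

**Decline scenarios.** `terrapop.scenario_engine` encodes eleven candidate
decline mechanisms (hurricane-year losses, adult-survival pulses, sustained
60/75/85% adult survival 2012–2018, recruitment failure from 2010, and
combinations), applies them to baseline yearly rates, and ranks them by
RMSE of the mean adult trajectory against a reference.

`terrapop.synthetic_data` generates study-shaped datasets (17 occasions
2001–2019 with a 2004–2005 gap, ~650 marked adults at a 1:1 sex ratio,
collapsing survival, effort-driven detection), so everything above runs and
is tested without the field data.

## Worked example

```python
import numpy as np
from terrapop import (VitalRates, hatchlings_per_female, fertility, build_matrix,
                      eigen_analysis, solve_Sj, stable_initialization, project,
                      builtin_scenarios, simulate_capture_histories,
                      default_template, build_design, fit)
from terrapop.synthetic_data import baseline_yearly_rates
from terrapop.scenario_engine import apply_scenario

v = VitalRates(S_a=0.9)
print(round(hatchlings_per_female(v), 4))   # 0.7096
print(round(fertility(v), 4))               # 0.4624
rep = eigen_analysis(build_matrix(v))
print(round(rep.lambda_dom, 4))             # 1.012
print(np.round(rep.stable_age, 3))          # [0.231 0.129 0.072 0.064 0.505]

ehs = simulate_capture_histories(default_template(), seed=1)   # 670 animals
f = fit(ehs, build_design(ehs, ("sex", "year"), ("sex", "effort")))
print(f.real_phi.query("sex == 'female' and year_start in (2003, 2017, 2018)")
       [["year_start", "estimate", "lcl", "ucl"]].round(3).to_string(index=False))
#  year_start  estimate   lcl   ucl
#        2003     0.852 0.794 0.896
#        2017     0.425 0.331 0.525
#        2018     0.390 0.270 0.525

vs = VitalRates(S_a=0.9, S_j=solve_Sj(1.0, v))          # stationary baseline
base = baseline_yearly_rates(vs, {y: 0.9 for y in range(2001, 2018)})
init = stable_initialization(500, eigen_analysis(build_matrix(vs)).stable_age, 2001)
sc = builtin_scenarios()[8]                             # adult survival 75% 2012-2018
s = project(init, apply_scenario(base, sc, vs), 17, n_reps=10_000, seed=2)
print(f"adults 2001 {s.adult_mean[0]:.0f} -> 2018 {s.adult_mean[-1]:.1f}")
# adults 2001 261 -> 2018 110.1
```

The fitted survival series reproduces the generating pattern (high ~0.85
early, collapse to ~0.4 by 2017–2018), and sustained 75% adult survival
from 2012 cuts the stationary adult female population by more than half in
seven years.

A `terrapop` console script wraps the same steps:
`terrapop simulate`, `terrapop fit`, `terrapop project`,
`terrapop scenarios` (run `terrapop --help`). Every run writes a JSON
manifest with the seed and a config hash.

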
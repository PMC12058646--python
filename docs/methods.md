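# Methods

## Survival model

Apparent survival and detection are estimated with the Cormack–Jolly–Seber
(CJS) model: open population, conditioning on each animal's first capture,
so the data carry no information about abundance or recruitment, only about
survival between occasions and detection at occasions. Each individual's
contribution is the product of interval survival terms from first to last
detection, Bernoulli detection terms in between, and the probability of
never being seen after the last detection, computed by the backward χ
recursion. Apparent survival confounds mortality with permanent
emigration; nothing in the likelihood can separate them.

Occasions are calendar years and may be unequally spaced (the study layout
has a 3-year interval spanning the two unsampled years). Interval survival
is the annual rate raised to the interval length, φ̃_t = φ_t^Δt, the same
convention Program MARK uses, so all reported survival is annualized.

Covariates enter additively on the logit scale. Survival: sex, year as an
interval factor, a standardized linear year trend, and a hurricane
indicator attached to the interval containing the storm (the autumn 2005
storm falls in the 2003→2006 interval, the autumn 2017 storm in 2016→2017).
Detection: sex, and annual effort hours standardized to mean 0, SD 1.
Effort enters as the annual total because estimates are annual; a per-hour
parameterization would only rescale the slope. No interactions are built:
the model the analysis targets is φ(sex + year), p(sex + effort), with
φ(sex + trend + hurricane) as the reduced form for a marginal hurricane
effect. A full year factor makes the hurricane indicator a sum of two year
columns, so that combination is rank-deficient by construction; the design
builder reports aliased columns (sequential column-order Gram–Schmidt, so
the later-added hurricane term is the one named) instead of silently
dropping them.

Fitting is quasi-Newton (BFGS) from five deterministic starts (all zeros,
±1 on each block's intercept), gradient tolerance 1e-8; the best optimum is
kept. The coefficient covariance is the pseudoinverse of a
central-difference observed information. Real-scale tables are
inverse-logits of the linear predictors with delta-method 95% intervals
computed on the logit scale, so bounds are always ordered and inside
[0, 1]. A real parameter is flagged inestimable when (a) its design vector
has a component in the numerical null space of the information — which
catches the structural terminal φ·p confounding of time-varying models —
or (b) its real-scale SE exceeds 0.45 or its |logit| exceeds 10, which
catches boundary estimates and data-poor years. For likelihood evaluation,
real-scale probabilities are clipped to [1e-12, 1 − 1e-12] so line searches
over the unbounded coefficient space cannot produce −∞; the clip is far
outside any region a converged fit occupies. Inside the optimizer,
encounter histories are collapsed to unique (sex, history) rows with
multiplicity weights — an exact rewrite of the likelihood that makes fits
roughly 20× faster at study scale.

## Projection matrix

The population model is female-only with classes for ages 0, 1, 2, 3 and a
pooled 4+ breeding stage. Fertility is the product of clutch size (6.7),
clutches per season (2.5), clutch survival (0.097), egg survival (0.8735)
and proportion female (0.5) — 0.7096 female hatchlings per breeding female
— times S_j^{9/12}, the juvenile survival discount for the roughly nine
months between hatching and the next annual census. Juvenile survival S_j
(default 0.565, the value recovered by calibrating projected λ to a
realized λ of 1.034 at high adult survival) sits on the 0→1 and 1→2
transitions; subadult survival equals adult survival S_a and sits on 2→3
and 3→4+. That placement follows the operational matrix used for
simulation; the alternative reading that keeps S_j through age 2 (on 2→3)
is available via `build_matrix_variant(v, sj_through_age2=True)`.

Retention in the pooled 4+ stage uses the fixed-stage-duration
approximation P_a = S_a(1 − (S_a/λ)^{T−1})/(1 − (S_a/λ)^T) with
T = l − m + 1 = 37 (maturity 4, longevity 40) and reference λ fixed at 1,
with the analytic limit S_a(T−1)/T at S_a = λ. The reference λ inside P_a
stays at 1 regardless of the λ used for the S_j calibration; those are two
different constructs. `solve_Sj` inverts λ_dom(A(S_j)) by Brent bracketing
on (ε, 1−ε) to 1e-10, including the dependence of F on S_j; λ_dom is
strictly increasing in S_j on this family, so the root is unique, and an
unreachable target reports the achievable λ range.

## Stochastic projection

Demographic stochasticity only: each annual transition draws binomial
survivors per class and Poisson recruits, with recruitment computed from
the *current-year* adult count (adult classes update first, then
n0 ~ Poisson(n4+ × F)). At λ = 1 this recruitment-after-update map shares
the unit eigenvalue with the standard Leslie matrix, so stationarity
carries over exactly. Environmental (good/bad year) variation, density
dependence and immigration are deliberately absent; replicate spread
therefore understates real-world uncertainty, especially at large
population sizes where demographic noise is relatively small.

Initial states round the stable age distribution to integers by largest
remainder (ties to the earlier class), preserving the total exactly. The
rounding perturbs the expected adult trajectory by less than one animal;
tests compare replicate means against the deterministic iteration of the
same integer initial state, which carries that transient. Replicates run
on generators spawned from a single master `SeedSequence`, so runs are
bit-reproducible and independent of replicate order. Summaries report the
adult (4+) class only, matching the study's "adult females" focus; the
replicate array is available for all-class summaries.

## Scenarios

The eleven built-in scenarios map one-to-one to the candidate decline
mechanisms: no hatchling survival in hurricane years; no fecundity in
hurricane years; no survival of any young class (ages 0–2 transitions) in
hurricane years; 50% adult survival in the single year after each
hurricane year (the window length is a choice — the source material does
not define it); 50% adult survival in 2010; no reproduction from 2010
onward (onset inclusive and configurable; "after 2010" and "from 2010
onward" are both used in the source and differ by one year); sustained
adult survival of 60%, 75% and 85% over 2012–2018; and the 75%/85%
variants combined with recruitment failure. Adult overrides propagate
through S_sa = S_a and recompute P_a at the overridden survival;
fecundity overrides replace F. Override years outside the baseline horizon
are ignored (the post-2017-hurricane year falls past the last simulated
transition). Application is idempotent and commutes for non-overlapping
overrides; contradictory overlaps raise an error.

Scenario–reference comparison is quantitative where the original was
visual: RMSE, maximum absolute deviation and Pearson correlation of mean
adult trajectories, with "best match" defined as minimum RMSE. All
scenarios in a run share one master seed, so ranking differences reflect
the overrides, not sampling noise.

## Synthetic data

The generator emulates the study's capture process: 17 annual occasions
2001–2019 with the 2004–2005 gap, hurricane flags on the 2006 and 2017
occasions, ~650 marked adults entering front-loaded over the years at a
1:1 sex ratio, annual adult survival high (~0.9) early and collapsing to
0.22–0.36 by the 2018 interval, and detection following a logit-linear
effort law spanning roughly 0.1–0.75 across the study's effort range
(3.6–50 h). Entry is the marking event; subsequent detection is Bernoulli
while alive. These defaults were chosen once to echo the study's scale and
power. What the generator does not emulate: temporary emigration (which
biases apparent survival low in real data), tag loss, within-year capture
heterogeneity, morphometric growth, and spatial structure — so passing
tests demonstrate estimator correctness under the data model's own
assumptions, not robustness to their violation.

`simulate_decline_study` closes the loop: it projects a true population
under a scenario, simulates the 4+ class at the individual level (adult
annual survival P_a, within 0.003 of S_a at the rates used), thins each
year's living adults by the detection law, and returns both the truth and
the observed encounter set, so the full estimate–project–rank chain can be
validated against known generating mechanisms.

## Problem sizes and numerical choices

Test and acceptance runs use 10,000 replicates for projection envelopes,
3,000 marked animals × 10 occasions × 50 replicate fits for CJS interval
calibration, and exhaustive/randomized sets of ≤ 4 occasions and ≤ 5
individuals for likelihood-vs-enumeration checks at 1e-9. Monte-Carlo
comparisons use 3 standard errors of the replicate mean. Eigen identities
are held to 1e-10, the S_j solve to 1e-10, CJS gradient convergence to
1e-8. Ties in largest-remainder rounding go to the earlier age class;
degenerate matrices (zero fertility or broken subdiagonal) still return
eigen results but carry a non-primitivity flag.

## Limitations

Apparent survival cannot separate death from permanent emigration, so
"decline in survival" scenarios are equally consistent with removal or
departure. The matrix borrows clutch/egg survival and the S_j calibration
from a northern population; absolute abundance levels are therefore
indicative, and only relative trajectories should be interpreted. The
scenario ranking is pattern-matching, not likelihood-based model selection:
it identifies which mechanism best reproduces a trajectory, not the
probability that the mechanism is true.
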
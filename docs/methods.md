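# Methods

This note documents the models implemented in `corvgrowth`, the conventions
and defaults behind them, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Growth models and conventions

Five length-at-age curves are implemented exactly as parameterised in
`corvgrowth.models`. Ages are real-valued years; input records carry
integer ages (annulus counts) and no fractional-age or birthdate adjustment
is applied. Lengths are total length in mm.

Two conventions deserve note:

- **Gompertz.** The default ("printed") form is
  `L(t) = L∞ exp(−(1/K) e^{−K(t−t0)})`, which satisfies
  `L(t0) = L∞ e^{−1/K}`. The textbook form without the 1/K factor
  (`L(t0) = L∞/e`) is available via `gompertz_form="standard"` on
  `predict_length` and `fit_model`. The two differ only by a reparameterised
  t0 when K is held fixed, but fitted parameter values are not comparable
  across forms, so the choice is explicit per call.
- **Schnute.** Only the `a ≠ 0, b ≠ 0` curve family is implemented. Its four
  endpoint constants (T1, L1, T2, L2) are data-derived — the observed
  minimum/maximum age and length — not free parameters, and the curve passes
  through both endpoints exactly for any (a, b). The family's asymptote
  requires a limit expression that this package deliberately does not
  evaluate; `asymptotic_length` returns `None` for it and model averaging of
  L∞ excludes it (its weight is renormalised away over the remaining
  models).

## Fitting

Parameters are estimated by Levenberg–Marquardt least squares (lmfit's
`leastsq`) on the raw residuals `length − L(age)`. Box bounds stabilise the
flexible models without binding at any realistic optimum: L∞ ∈ (0, 3·L_max],
rates K and a ∈ (0, 10], the Schnute–Richards exponent c ∈ (0, 10]; t0,
t_infl, b and α are unbounded. A fit whose optimum touches a bound is
flagged (`at_bounds`), not rejected.

Starting values are deterministic heuristics: L∞⁰ = 1.05·L_max, rates 0.3/y,
locations 0; Schnute (a⁰, b⁰) = (0.3, 1); Schnute–Richards
(α⁰, a⁰, b⁰, c⁰) = (−0.9, 0.3, 0.1, 1). Because the flexible models have
multimodal RSS surfaces, fitting is multi-start: the free starting values
are perturbed multiplicatively by log-normal factors (sd 0.2 on the log
scale, seeded) and the lowest-RSS converged attempt wins. Defaults are 25
restarts for Schnute–Richards and 5 elsewhere.

The Gaussian log-likelihood is the concentrated form at the least-squares
optimum, `−(n/2)(ln(2π σ̂²) + 1)` with `σ̂² = RSS/n`, including the 2π
constant so absolute criterion values are comparable across software. The
parameter count used by the criteria is the number of free structural
parameters plus one for σ², giving k = 4 for von Bertalanffy, Gompertz and
logistic, k = 3 for Schnute and k = 6 for Schnute–Richards.

Confidence intervals are Wald intervals from the covariance of the
least-squares surface at the optimum (normal quantiles, residual-variance
scaled). Entries with singular or non-finite curvature are flagged
degenerate with infinite bounds rather than fabricated. Profile or
bootstrap intervals are not provided.

## Model selection

`AICc = AIC + 2k(k+1)/(n−k−1)` with `AIC = −2 log L + 2k`, and
`BIC = −2 log L + k ln n` (natural log). Akaike weights are computed from
ΔAICc. Selection tables sort by ascending AICc with ties broken by smaller
k, then model name. Two averaging paths are exposed: `model_average_linf`
renormalises the weights over the L∞-bearing models of a fitted table, and
`weighted_average_linf` is the plain dot product for externally supplied
(e.g. published, rounded) weights.

## Bias indicators

- **Bolstering** draws `target − n_obs` lengths per age class from
  Normal(class mean, class SD with n−1 denominator), rejecting non-positive
  draws (lengths are physical; at realistic means/SDs the rejection rate is
  negligible). Original records are preserved verbatim as a prefix.
  Downsampling is refused, and a single-record class (undefined SD) is an
  error directing the user to merge classes or supply an SD. One seeded
  bolstering replicate is the default; Monte-Carlo replication across seeds
  (as in the test suite) characterises the downstream scatter. Note a
  structural caveat: bolstering copies each class mean's sampling error into
  every simulated record, creating systematic per-age signal that flexible
  models can absorb — near-ties between an inflexible generating family and
  a flexible competitor on bolstered data are expected, not anomalous.
- **Froese–Binohlan check** uses base-10 logarithms,
  `L∞ = 10^(0.044 + 0.9841 log10 L_max)`, mm in / mm out. At
  L_max = 1,013 mm it evaluates to 1,004.2 mm.
- **Histograms** are left-closed right-open bins anchored at zero, 10 mm
  wide for lengths, unit bins for ages.

## Per-recruit model

A discrete annual recursion over ages 1..A_max with N₁ = 1 and
`N_{a+1} = N_a (1 − u_a) e^{−M}`, where u_a is 0 before the maturity age
a_R, E_YA for young adults (a_R ≤ a < a_OA) and E_OA from a_OA on. By
default harvest is taken before natural mortality within a year and
spawning is measured post-harvest — the configuration for a fishery that
targets spawning aggregations; both orderings are config flags.
`YPR = Σ N_a u_a W_a`, `SSBR = f Σ_{a≥a_R} N_a (1 − u_a) W_a`, with
`W_a = lw_a · L(a)^{lw_b}` from the configured growth scenario (negative
predicted lengths clamp to zero weight). YPR_max and its argmax come from a
grid scan (default step 0.005 in E, bounding the argmax error by half a
step).

Defaults follow the Gulf Corvina life history: a_R = 2 y, a_OA = 5 y,
A_max = 8 y (the oldest observed age; configurable up to the documented
maximum of 9), female fraction 0.5, current E_OA = 0.825/y. Natural
mortality and weight–length coefficients have **no defaults** — they must
be supplied. The example configuration uses illustrative values chosen from
standard rules: M = 0.47/y (a longevity-based estimate with t_max = 9 y)
and a generic isometric sciaenid weight–length relation
(lw_a = 9.5·10⁻⁹ kg·mm⁻³, lw_b = 3.0). They are placeholders for
stock-specific estimates, not endorsed values.

Two structural consequences of the defaults are worth knowing. With
E_YA = 0, yield is drawn only from ages at or past a_OA, where little
growth remains relative to M; YPR is then monotone increasing in E_OA and
attains its maximum at E = 1, so YPR/YPR_max comparisons across growth
scenarios compress toward 1. An interior YPR maximum — and the familiar
"current E is well above the YPR-maximising E" diagnostic — emerges only
when young adults are also exploited (set E_YA > 0). The FNSSBR comparison
is robust to this: a growth scenario with uniformly lighter old fish
concentrates spawning biomass at younger, less-exploited ages and therefore
reports a higher (healthier-looking) depletion ratio, which is exactly the
false-resiliency hazard of fitting a flexible model to size-truncated data.

## Synthetic data

The generator emulates the structure the analysis assumes: integer ages on
1–8, lengths = truth curve + Normal(0, noise_sd(age)) with rejection below
a 50 mm floor (and above an optional cap), and three age-sampling designs.
The default bimodal design mixes a young bycatch component (discretised
Normal(1.5, 0.5), 30% weight) with a directed-fishery component
(discretised Normal(5, 1.3), 70%); the fishery spread was set so that a
749-record draw keeps every age class at or below 200 records, consistent
with bolstering every class *up* to 200. Default noise is 40 mm, scalar;
per-age vectors are supported. `sampling="uniform"` is stratified — exactly
equal per-age counts — for ideal-sampling experiments.

The optional `length_cap` implements size-selective removal by rejection
above the cap. This matters for directional-bias experiments: truncating
*ages* alone leaves a correctly specified growth model identified and
(asymptotically) unbiased, so the classic L∞-down/K-up distortion only
appears when large fish are also missing *within* ages — the cap provides
that mechanism. The default experiments truncate above age 6 and 750 mm,
magnitudes typical of a heavily exploited stock.

What the generator does not emulate: real per-age frequencies (unpublished
for the motivating dataset — the mixture is illustrative), gear-selectivity
mechanics, inter-annual (e.g. ENSO-driven) growth variation,
heteroscedasticity of real length-at-age scatter, or ageing error. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated sampling designs, not fidelity of any particular
field dataset.

## Numerical choices and degenerate inputs

- Zero-residual fits guard σ̂² at 10⁻³⁰⁰ so the log-likelihood stays finite.
- AICc raises a domain error when n ≤ k + 1 (correction undefined).
- Fitting requires at least as many distinct ages as structural parameters.
- A degenerate all-one-age sampling mixture is permitted but warned about.
- The per-recruit E grid must include 0 (NSSBR is undefined otherwise).
- Selection-table ties (equal AICc) order by smaller k, then model name.
- All stochastic stages take explicit integer seeds; nothing derives
  randomness from the clock. Test and example problem sizes (e.g. 100
  replicates at n = 1,600 for recovery experiments, 20 seeds for bolstering
  Monte Carlo) were chosen to give stable Monte-Carlo margins at
  interactive runtimes.

## Known limitations

- Only the `a, b ≠ 0` Schnute family; no seasonal, sex-specific or
  tag-recapture growth formulations; no errors-in-age modelling.
- Wald intervals only; they can be poor for the weakly identified L∞ of
  flexible models on truncated data (flagged, not fixed).
- The per-recruit model is a single-cohort equilibrium calculation: no
  stock–recruit dynamics, no plus-group, no estimation of exploitation
  rates from catch data.
- Report schema validation relies on pydantic; the shipped
  `report_schema.json` is generated from the same model and kept in sync by
  a test.
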
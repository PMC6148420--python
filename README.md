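# corvgrowth

Growth modelling, multimodel selection, sampling-bias diagnostics and
per-recruit assessment for age–length data from exploited fishes — built
around the case of the Gulf Corvina (*Cynoscion othonopterus*), a
heavily exploited sciaenid of the northern Gulf of California whose fishery
samples are bimodal (bycatch of young fish plus a directed fishery targeting
~5-year-olds near 700 mm) and short on old, large individuals.

It is a library first (import `corvgrowth`), with short narrative scripts in
`examples/` and a thin `corvgrowth` command-line interface for running the
whole pipeline from a shell.

## What it does

**Five growth curves.** Length-at-age L(t) in mm TL:

- von Bertalanffy: `L(t) = L∞ (1 − e^{−K (t − t0)})`
- Gompertz: `L(t) = L∞ e^{−(1/K) e^{−K (t − t0)}}` (a standard form without
  the 1/K factor is selectable by flag)
- logistic: `L(t) = L∞ / (1 + e^{−K (t − t_infl)})`
- Schnute (a, b ≠ 0): `L(t) = [L1^b + (L2^b − L1^b) (1 − e^{−a (t − T1)}) /
  (1 − e^{−a (T2 − T1)})]^{1/b}`, with (T1, L1), (T2, L2) pinned to the
  observed age/length extremes
- Schnute–Richards: `L(t) = L∞ (1 + α e^{−a t^c})^{1/b}`, flexible enough to
  describe biphasic growth

**Fitting and selection.** Each model is fit by Levenberg–Marquardt
nonlinear least squares (seeded multi-start for the flexible models), with
Wald confidence intervals. Models are compared by small-sample AICc and BIC
(`AICc = −2 log L + 2k + 2k(k+1)/(n−k−1)`, `BIC = −2 log L + k ln n`, with
k counting structural parameters plus the residual variance) and by Akaike
weights `w_i = e^{−Δ_i/2} / Σ e^{−Δ_k/2}`, which also drive model averaging
of L∞.

**Bias indicators.** Frequency histograms (10 mm length bins, unit age
bins); per-age statistics; *bolstering* — simulating the ideal sampling
outcome by topping every age class up to 200 records with draws from
Normal(class mean, class SD) and refitting; and the Froese–Binohlan
empirical check `log10 L∞ = 0.044 + 0.9841 log10 L_max` relating the
largest sampled fish to the asymptotic length.

**Per-recruit model.** A discrete annual cohort model with natural
mortality M and stage-specific annual exploitation rates (maturity at age
a_R, old-adult stage from a_OA) yields yield-per-recruit YPR(E) and female
spawning-stock-biomass-per-recruit SSBR(E); FNSSBR = SSBR/SSBR(0) is the
depletion ratio. Any growth scenario plugs in through a weight–length power
law, so the assessment consequences of choosing a biased growth model are
measured directly.

**Synthetic data.** A seeded generator with a known true curve,
age-specific Gaussian scatter, and uniform / bimodal / custom age sampling
(optionally truncated above a length cap), plus generate-and-refit recovery
experiments reporting per-parameter bias and RMSE.

## Worked example

```sh
python examples/02_fit_and_select.py
```

```
simulated 749 records, ages 1-8, lengths 171-914 mm

           model  k    aicc  delta_aicc  weight     bic  delta_bic
 von_bertalanffy  4 7576.25        0.00    0.81 7594.67       0.00
schnute_richards  6 7579.16        2.91    0.19 7606.76      12.09
        gompertz  4 7603.34       27.09    0.00 7621.76      27.09
        logistic  4 7654.09       77.84    0.00 7672.52      77.84
         schnute  3 8229.90      653.65    0.00 8243.72     649.05

model-averaged L_inf: 920.8 mm (truth: 900 mm)
```

The sample was simulated from a von Bertalanffy truth (L∞ = 900 mm,
K = 0.3/y, t0 = −0.2 y) with the bimodal fishery sampling pattern. The
selection table ranks models by AICc; ΔAICc is the distance to the best
model and the Akaike weights convert those distances into relative
evidence (0.81 for the generating family here). The weight-averaged
asymptote (920.8 mm) pools L∞ across the models that define one.

The other scripts follow the same pattern: `01` evaluates the five curves
at published parameter sets, `03` runs the bias indicators, `04` measures
the L∞-down/K-up bias induced by age/size-truncated sampling, `05`
propagates five growth scenarios through the per-recruit model.

A full pipeline run from the shell:

```sh
corvgrowth simulate --seed 1 --n 749 --out data.csv
corvgrowth run-all --data data.csv --config examples/analysis_config.yaml \
    --seed 1 --out results/
```

writes fit JSONs, selection tables, indicator tables, the bolstered
dataset, per-recruit curves and a validated `report.json` under
`results/`.

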
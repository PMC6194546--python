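# Methods

## Demand model

Per-capita cigarette consumption of the population aged 15+ in country *i*,
year *t* follows a constant-elasticity demand equation in logs:

```
ln C_it = β₁ᵢ + β₂ ln P_it + β₃ ln GNI_it + β₄ FCTC_it + ε_it
```

* `C_it` — packs per capita (15+), strictly positive;
* `P_it` — real retail price of a 20-stick pack, US$, CPI-deflated;
* `GNI_it` — real GNI per capita, US$ (Atlas-method style);
* `FCTC_it` — 0/1 ratification status of the WHO Framework Convention on
  Tobacco Control (absorbing: once ratified, always 1);
* `β₁ᵢ` — country fixed effects capturing time-invariant heterogeneity
  (consumption culture, measurement conventions);
* `β₂` — the price elasticity of demand, the quantity of interest.

Because price is formed partly by demand conditions it is treated as
endogenous; the identifying assumption is that last year's real price and
last year's CPI affect current consumption only through current price.

## Estimator

`fit_fe_2sls` applies the within transform (subtracting country means, which
absorbs β₁ᵢ) and then 2SLS with excluded instruments `ln P_{t−1}` and
`ln CPI_{t−1}`; lag construction consumes the first usable year of every
country, and lags are only formed across consecutive calendar years.
Countries reduced to fewer than two observations are dropped with a logged
warning; nothing is excluded silently.  With `iv=False` the same routine
returns the within-OLS estimator.

**Covariance.** Cluster-robust by country with the CR1 small-sample factor
`G/(G−1) × (N−1)/(N−k)`.  `k` counts the slope parameters only: with that
convention the estimator reduces exactly to the HC1 sandwich when every
observation is its own cluster, and it matches the common panel-software
convention of not charging absorbed intercepts against the residual degrees
of freedom.  Confidence intervals in the validation studies use t critical
values with G−1 degrees of freedom (G = number of clusters).

**R².** The reported `r_squared` is the within-R² of the second stage,
computed from residuals at the *actual* (not fitted) regressors; under IV it
can be negative and is reported as computed.

**Random effects.** The Hausman comparator is Swamy–Arora GLS:
σ²_e from the within residuals (df N − G − k), σ²_u = max(0, σ²_B − σ²_e/T̄)
from the between regression on country means (df G − k − 1), T̄ = N/G —
exact for balanced panels, a standard simplification otherwise — and
per-country quasi-demeaning weights θᵢ = 1 − sqrt(σ²_e/(Tᵢσ²_u + σ²_e)).
A negative variance component is truncated at zero with a logged warning.
Limiting behaviour is tested: σ²_u = 0 reproduces pooled OLS, large σ²_u
drives θ → 1 and the RE slopes toward the within slopes.

**Hausman test.** Classical form H = Δb′(V_FE − V_RE)⁻¹Δb over the three
slopes, with *conventional* (iid) covariances on both sides, as the test's
asymptotics require; χ²₃ upper-tail p-value.  When V_FE − V_RE is not
positive definite (common in finite samples, and typical under the
alternative) the Moore–Penrose pseudo-inverse is used and the result is
flagged `indefinite`, never hidden.

**Weak identification.** The first stage regresses within-transformed
`ln P` on the within-transformed excluded instruments plus exogenous
regressors; the statistic is the cluster-robust Wald test of the excluded
instruments divided by their number.  With a single endogenous regressor
this equals the Kleibergen–Paap rk Wald F.  Perfect relevance (zero
first-stage residuals) is reported capped at 10⁶.  An overidentification
(Sargan-type) test is not implemented.

**Income groups.** Countries are assigned by final-year GNI per capita to
six bins with edges at US$1000/2000/3000/4000/6000; a value exactly on an
edge goes to the higher group.  Groups with a single country cannot support
clustered inference and are skipped with a warning.

## Synthetic data generator

`generate_panel` realizes the demand equation exactly with known
coefficients.  Defaults are the validation study conditions: 22 countries ×
17 years (1999–2015), β₂ = −1.304, β₃ = 0.769, β₄ = −0.103 (the largest
published income group's magnitudes, the hardest recovery target),
country-intercept dispersion 0.5 around a mean of 1.

* **Price**: ln P = country base (N(ln 1.2, 0.5²)) + stationary AR(1)
  deviation, ρ = 0.9, innovation SD 0.08.  Persistence makes the lagged
  price a strong instrument; ρ = 0 makes it uninformative, which the
  weak-instrument tests exploit.
* **GNI**: geometric growth, country level log-uniform on US$500–12 000 and
  drift U(0, 5%)/yr, so the income bins are populated and distinguishable.
* **CPI**: smooth per-country inflation path (U(2, 8%)/yr with small yearly
  jitter), base 100.  It enters the demand equation nowhere; prices are
  already real.  It exists to provide the second instrument.
* **FCTC**: one adoption year per country, uniform on 2003–2010, absorbing.
* **Error**: ε = SD × (√ρ_c · u_i + √(1−ρ_c) · e_it) with ρ_c = 0.3 by
  default — an equicorrelated country component plus idiosyncratic noise,
  the simplest structure consistent with clustering inference by country.
  Default noise SD 0.05.
* `alpha_price_corr` correlates the country intercepts with the country's
  mean log price; nonzero values violate the random-effects assumption and
  drive the Hausman power study.

What the generator does **not** emulate: real countries' price levels or
trajectories, measurement error in consumption (tax-paid sales miss illicit
trade), common macro shocks across countries, or non-stationary income
paths.  Passing recovery tests therefore show the estimator is correct under
the model's own assumptions, not that the published elasticities are right
for the region.

### Validation study sizes

* Recovery/coverage: 500 replicates at the default conditions; the mean
  estimate must lie within ±0.02 of β₂ and the 95% CI (t, G−1 df) must cover
  within [0.90, 0.98].  Observed in development: bias ≈ +0.002,
  coverage ≈ 0.94.
* Hausman size: 500 replicates, exogenous intercepts; power: 200 replicates
  at intercept–price correlation 0.8.  Both use residual SD 0.15.  That
  noise level is where the FE/RE distinction is statistically meaningful:
  with very small residual noise the quasi-demeaning weight θ → 1 and RE
  collapses onto FE, a regime where the classical test has little power by
  construction.  The power alternative (correlation 0.8) is a deliberately
  detectable violation, as is standard in power studies.

## Policy simulator

A one-shot comparative static from the latest observed year's baseline; no
multi-year cohort projection, brand switching, down-trading or illicit-trade
response.

* **Consumption**: dC = β₂ · dP, the *linear* response, not the
  constant-elasticity power form (1+dP)^β₂ − 1.  The linear form is what
  reproduces the published country cells exactly (e.g. −1.304 × 50.96% =
  −66.45%); the power form does not.
* **Revenue**: baseline excise take per pack is τ × retail price with
  τ = specific + ad valorem share as printed; the entire price increment is
  treated as new specific excise (ad valorem is not re-applied to the new
  price), so dRevenue = ((τ+dP)/τ)(1+dC) − 1.  This reconstruction
  reproduces 17 of 20 published mean-scenario revenue cells to ±0.01 pp;
  Laos, Mongolia and India disagree by up to 0.8 pp, consistent with their
  published tax shares being rounded — documented here, not absorbed.
  τ = 0 or unknown τ (Maldives; Bhutan) yields an undefined revenue change,
  rendered "–", never 0.
* **Smokers**: reduction = prevalence × population(15+) × |dC|; the whole
  consumption response is attributed to quitting (the prevalence margin),
  which is what makes the mortality step applicable.
* **Mortality**: MAF = death-risk × Σ age-share × avoidance-weight, with
  avoidance weights 0.95/0.75/0.70/0.50/0.10 for ages
  15–29/30–39/40–49/50–59/60+ and baseline death risk 0.5.  The death risk
  is the conventional "half of continuing smokers die of smoking" figure;
  it is consistent with the implied country factors (0.25–0.37), all ≤ 0.5.
  Averted deaths = quitters × MAF.
* **Historical increments**: year-over-year fractional changes across
  consecutive years only; the mean averages *all* changes by default
  (a `positive_only` flag restricts to increases — whether the reference
  analysis did so is not documented, hence the option).
* **Regional aggregation**: the regional price increment is the unweighted
  mean (this reproduces the published 9.51%); person counts are summed.
  For the regional consumption and revenue *percentages* no weighting
  reproduces the published aggregates (−3.56%, +16.20%; unweighted means
  give −3.20%, +28.9%), so the weighting is configurable and those two
  aggregates are not treated as reproduction targets.
* Percentages are carried at full precision and rounded only for display.

## Bundled reference inputs

Three transcribed tables ship in `cigtaxsim/data/`: the countries' excise
structure and prevalence, the six income groups' estimates, and the published
simulation outcomes (the snapshot surface).  The published group elasticities
themselves are **not** desk-reproducible — the underlying market-research
panel is proprietary — so the estimator is validated by oracle equivalence
and Monte-Carlo recovery instead, and the simulator consumes the published
elasticities as inputs.

`policy_inputs_synthetic.csv` is a constructed input table: population 15+
is backed out of the published mean smoker reduction
(pop = reduction / (prevalence × |dC|)), and age-band shares are calibrated
(by interpolating between a uniform and a degenerate age distribution) so
the country's MAF equals the implied deaths/quitters ratio.  Those two
inputs are not published anywhere in the reference tables; the file is
synthetic in that sense and named accordingly.  Internal consistency of this
inversion is itself a tested property (max/mean ratios agree to <0.1%;
implied MAFs all lie in [0, 0.5]).

## Numerical and interface conventions

* All machine-readable files use fractions; only the report layer multiplies
  by 100.  The transcription fixture `table3_expected.csv` is the one
  exception: it stores the published values in their printed percent units,
  in columns suffixed `_pct`.
* Missing values are empty cells surfaced as undefined (`None`), never 0.
* Panels regenerate byte-identically from the same seed; panel CSVs
  round-trip at full float precision (`%.17g`, round-trip parsing).
* Rank-deficient designs raise a `RankError` naming the columns; fewer than
  two countries raises before any clustered quantity is formed.

## Known limitations

* The simulator's linear consumption response is a local approximation; at
  the largest historical increments (≈88%) it can imply near-total
  consumption collapse for highly elastic groups.
* The Swamy–Arora T̄ = N/G simplification is exact only for balanced panels.
* Cluster-robust inference relies on a moderate number of clusters; with
  very few countries per income group (minimum 2) the SEs are noisy, which
  is why the per-group fits carry their cluster counts.
* No overidentification test; no dynamic panels or GMM.
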
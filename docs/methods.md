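# Methods

## Model structure

qalysim is a proportional multistate life table. A closed cohort (no births
or migration), stratified by sex and single year of age from 15 upwards, is
propagated through annual cycles. Each stratum carries one prevalence state
per modelled disease alongside its survivorship; diseases are independent
of one another (no comorbidity interaction, no diabetes-to-CVD risk
linkage). All rates are annual risks (probabilities); any hazard-form input
must be converted at load time via `1 − exp(−h)`.

Within a cycle the state updates are ordered: incidence → disease deaths →
remission → other-cause deaths. Disease deaths are removed from the
diseased pool only; other-cause deaths are removed proportionally from the
diseased and disease-free pools, which makes the residual rate cancel from
the prevalence update:

```
p(t+1) = (N p + N(1−p)i − N p f − N p w) / (N − N p f)
```

The residual (other-cause) mortality schedule is computed from the *input
tables*: all-cause mortality minus the sum over diseases of table prevalence
× case fatality, floored at zero with a logged warning. It is identical in
the baseline and scenario arms. Scenario-arm total mortality is the
evolving disease deaths plus this fixed residual, so lowering incidence
genuinely averts deaths and extends person-years. This is the standard
lifetable decomposition; recomputing the residual from the scenario's own
prevalences would pin total mortality to the all-cause schedule and no
intervention could ever save a life.

Person-years use a half-cycle correction, `PY(t) = N(t) − deaths(t)/2`.
Mean utility is the stratum's background utility (already net of
unmodelled-disease morbidity) minus prevalence-weighted disease utility
decrements, clipped to [0, 1].

Inputs arrive in 5-year age bands and are expanded to single years
piecewise-constant (population counts split evenly). Cohorts older than the
oldest band keep using its rates — an open-ended terminal band — and
lifetime-horizon runs continue until every stratum falls below 10⁻⁹ of its
initial size or the oldest cohort reaches age 110, whichever comes first.
The synthetic bundle's oldest band starts at 95, so the terminal band
covers ages 95+; with a design target of "terminal age ≈ 100" this is the
same mechanism anchored at the top of the available data.

## Risk-factor pathways

**Continuous (salt → blood pressure → IHD/stroke).** The per-stratum mean
change in salt intake (g/day) is multiplied by a per-stratum dose-response
slope (mmHg per g/day) to give a systolic blood pressure change, and the
incidence multiplier is log-linear: `RR_per_mmHg ^ ΔSBP`. The model acts on
the population *mean* shift rather than integrating over the full exposure
distribution; the mean shift is the operative quantity reported for this
kind of intervention, and the distribution-integral alternative is a
non-goal. Age attenuation of the blood-pressure relative risks is carried
entirely in the per-stratum RR table — no functional form is imposed. The
same machinery serves any mediated continuous exposure (BMI, cholesterol),
but only blood-pressure parameter tables ship with the synthetic bundle.

**Categorical (physical activity).** Four categories — sedentary
(0 min/week of moderate activity), under-active (<60), active (60–150),
recommended (≥150) — with per-disease relative risks referenced to
"recommended". A scenario moves a participating fraction of the population
between categories via a row-stochastic transition matrix; participation
applies only to the non-sedentary mass (programme participants are by
definition not sedentary) and is uniform within a stratum. The incidence
multiplier is `1 − PIF` with the potential impact fraction computed from
the baseline and post-intervention distributions.

Scenario effects on incidence are immediate once phased in: no lag between
the risk-factor change and the disease-risk change is modelled (none is
specified for these interventions; for cancers a multi-year lag would be
biologically plausible and would shrink 10-year gains).

## Scenarios

**Salt reformulation.** Food-diary microdata (person × food group, grams
consumed, baseline and target salt densities) are reformulated to target
densities; per person `Δsalt = Σ grams × (target − baseline)/100` assuming
no other dietary change, and per stratum the shift is the mean of person
deltas with standard error `SD/√n` (used as the normal effect-size
distribution in Monte Carlo). Costs: industry pays products × unit cost
(defaults 20,000 × £29,953), phased evenly over three years (a one-year
phase-in is the sensitivity configuration); government pays annual
monitoring — a food-purchase panel subscription (£91,588/yr) plus a
biannual urinary sodium survey (£327,289, annualised) — and administration
(£570,892/yr) for *every* year of the horizon, on the reasoning that
surveillance continues after reformulation completes. Monetary defaults are
2014 GBP.

**Leisure-centre access.** Baseline four-category activity distributions,
a per-stratum participation fraction, and a participant transition matrix
define the perturbation (full effect from year one; the scheme has no
stated phase-in). Government pays per participant: £53.80 in year one,
£29.80 thereafter, with triangular uncertainty (43.50, 53.80, 85.90) and
(24.00, 29.80, 48.10). An age mask restricts effects to ages 16+ without
changing the cohort itself.

## Economics

Discounting divides year *t* by `(1 + r)^(t−1)` — year one undiscounted —
at r = 1.5%/year for costs and health outcomes alike. The year-one
convention was chosen because it reproduces the salt programme's total
discounted implementation cost from its printed components end-to-end;
it is exposed as the model's convention and sensitivity configurations can
set other rates.

NHS costs are per-prevalent-case annual disease costs (per stratum, looked
up at the cohort's current age) plus background costs unrelated to the
modelled diseases. Social-care costs are a function of age and quality of
life; the functional form here is this package's own choice:

```
12 × base monthly cost × eligibility(age) × (1 + sensitivity × (1 − mean utility))
```

per person-year, plus unrelated background social costs. All coefficients
live in the input tables, never in code. The form is monotone in
(1 − utility) by construction. A consequence worth knowing: a beneficial
intervention raises late-life person-years, and whether social care shows a
net saving depends on the balance between the quality-of-life saving and
the cost of those extra years.

Classification: *dominant* iff ΔC < 0 and ΔE > 0; *dominated* iff ΔE ≤ 0
and ΔC ≥ 0 (not both zero); otherwise the ICER `(C_b − C_a)/(E_b − E_a)`.
A scenario identical to doing nothing (both deltas exactly zero) raises an
undefined-comparison error rather than reporting 0/0. Return on investment
is reported in two conventions that disagree: the headline
`(NHS + social savings)/C_i` (pounds back per pound spent) and the signed
net `(C_b − C_a)/C_i = 1 − ROI`. Both are exposed (`roi`, `roi_net`)
because the field uses both and they answer different questions; the
package does not adjudicate. Time to cost saving is the first year in
which cumulative discounted savings reach cumulative discounted
intervention costs, or none.

HALYs are provided for cross-checking QALYs: person-years weighted by
`1 − background disability − Σ prevalence × disability weight` (floored at
zero). Feeding the utility decrements in as disability weights and
`1 − baseline utility` as background makes HALYs equal QALYs by
construction, which the tests exploit as an exact identity.

## Uncertainty analysis

One root seed spawns a counter-based substream per iteration
(`default_rng([seed, i])`), so runs are bit-identical under a fixed seed
and earlier iterations are unchanged when the iteration count grows. Only
scenario parameters carry declared distributions (effect sizes,
per-participant costs); the baseline arm is deterministic and computed
once. Percentiles use linear interpolation; ratio quantities (ICER, ROI)
are summarised per iteration — medians of ratios, never ratios of medians.
Dominant iterations count as below any positive cost-per-QALY threshold.
The percentile estimator and random-number discipline are documented
conventions, not claims about any other implementation.

## Synthetic data

The generator emulates the *structure* of the English sources, not their
values: per-person food-group diaries whose salt densities sit above
reformulation targets (defaults give mean intakes of 8.0 g/day for men and
6.2 g/day for women, falling slightly with age, and a 15% density cut in
five of six food groups — a shift of roughly −1 g/day); four-category
activity distributions in which younger and male strata are more active;
Gompertz-style mortality and incidence growth with age; linearly declining
utilities; logistic care-home eligibility concentrated above age 85 at
£2,700/month. Case fatalities are rescaled so summed disease deaths stay
below half of all-cause mortality in every stratum, guaranteeing a positive
residual by construction. Population counts are England-like in total
(~33 m adults) and separable from all rates via a single scale factor.

What passing tests on this bundle do show: conservation of the cohort,
correct difference equations, correct pathway arithmetic, directional
sanity (beneficial interventions gain QALYs and slightly raise the
incidence of unrelated diseases through longer survival), and exact
reproduction of the salt programme's self-contained cost arithmetic. What
they do not show: calibration to real English epidemiology, secular trends
(baseline rates are held constant; no age–period–cohort projection),
regional heterogeneity, dietary substitution, or scheme attrition — so
absolute QALY and cost levels on synthetic data are illustrative, not
predictions.

## Numerical choices and problem sizes

* Prevalence updates are clamped to [0, 1] and residual mortality floored
  at 0, each with a logged warning — both indicate inconsistent inputs, not
  normal operation.
* Cohort accounting is exact by construction (`alive(t+1) = alive(t) −
  deaths(t)` in floating point, verified to 10⁻⁹ relative in tests).
* CSV round trips are bit-exact: fixed column order, canonical row order
  (male before female, ascending age), shortest round-trip float
  formatting, and correctly-rounded float parsing on load.
* Default problem sizes: 2 sexes × 17 five-year bands expanded to 170
  single-year strata, 11 diseases, 10-year horizon (95 cycles for
  lifetime); 120 diary persons per stratum; Monte Carlo defaults to 2,000
  iterations, and the bundled reproduction script uses 200, chosen as
  comfortably sufficient for median and threshold-probability summaries of
  the narrow cost distributions involved.

## Known limitations

Disease independence; no exposure-to-risk lag; mean-shift (not
distributional) continuous pathways; a stylised social-care cost form; no
trend projection; synthetic rather than calibrated inputs. The two ROI
conventions disagree by construction and both are reported.
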
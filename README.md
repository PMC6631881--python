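# qalysim

A multistate life table simulator for estimating the cost-effectiveness of
population-level diet and physical-activity interventions from a health and
social care perspective. It is aimed at public-health modellers and health
economists who need to compare unrelated preventive policies — e.g. a
national salt-reformulation programme against subsidised leisure-centre
access — on a common footing: quality-adjusted life years (QALYs), NHS and
social-care expenditure, cost per QALY, and return on investment.

## The model

A closed adult cohort, stratified by sex and single year of age, is aged
through annual cycles. Each stratum carries a prevalence state for every
modelled disease (ischaemic heart disease, stroke, type 2 diabetes, seven
cancer subtypes, liver cirrhosis). With survivors *N*, prevalence *p* and
annual risks for incidence *i*, case fatality *f* and remission *w*, one
cycle of a disease updates as

```
new cases       = N (1 − p) i
disease deaths  = N p f
remitted        = N p w
p'              = (N p + new − disease deaths − remitted) / (N − disease deaths)
```

Other-cause mortality is the all-cause rate minus the disease deaths implied
by the input prevalences, held fixed across arms, so an intervention that
lowers incidence genuinely averts deaths. Person-years use a half-cycle
correction; the mean utility of a stratum is its background utility minus
the prevalence-weighted disease utility decrements.

Interventions act on disease incidence through risk-factor pathways:

* a **continuous exposure** (dietary salt, g/day) shifts systolic blood
  pressure (ΔSBP = Δsalt × mmHg-per-gram) and multiplies IHD and stroke
  incidence by `RR^ΔSBP`;
* a **categorical exposure** (physical activity in four categories:
  sedentary, under-active, active, recommended) acts through the potential
  impact fraction, `PIF = (Σ pᵢRRᵢ − Σ p'ᵢRRᵢ) / Σ pᵢRRᵢ`, with incidence
  multiplier `1 − PIF`.

Economics follow the convention `CE = (C_b − C_a) / (E_b − E_a)`, where
`E_b`/`E_a` are discounted QALYs with/without the intervention, `C_a` is
care expenditure without it and `C_b` adds the intervention cost `C_i`.
Costs and health outcomes are discounted at 1.5%/year (year one
undiscounted). When the intervention is cost saving, the return on
investment `(NHS + social-care savings)/C_i` is reported — pounds returned
per pound spent — together with the signed net form `(C_b − C_a)/C_i`.
Parameter uncertainty propagates through Monte Carlo simulation
(per-stratum normal effect sizes for the salt shift, triangular
per-participant costs for the leisure scheme), summarised as medians with
95% uncertainty intervals and threshold probabilities.

Because the original English input datasets (diet survey microdata,
activity survey, life tables, NHS programme budgeting costs) are not
redistributable, a seeded synthetic generator produces an England-like
bundle with the same statistical structure — per-person food-group diaries
with above-target salt densities, four-category activity distributions,
monotone age gradients — so the whole pipeline runs out of the box.

## Worked example

```python
import qalysim as qs

config = qs.SynthConfig(seed=1)
inputs = qs.generate_inputs(config)
diary, pa_base, pa_part, pa_trans = qs.generate_microdata(config)

salt = qs.build_salt_scenario(diary)
res = qs.evaluate_scenario(inputs, salt, horizon=10)
s, ce = res.summary, res.ce
print(f"QALY gain over 10 years : {s.delta_qalys:,.0f}")
print(f"NHS savings             : £{s.nhs_saving/1e6:,.1f} m")
print(f"Social care savings     : £{s.social_saving/1e6:,.1f} m")
print(f"Intervention cost (C_i) : £{s.c_i/1e6:,.1f} m")
print(f"Classification          : {ce.classification}")
print(f"Cost per QALY           : £{ce.icer:,.0f}")

mc = qs.run_monte_carlo(inputs, salt, n_iterations=200, seed=1)
q = mc.summary.quantities["delta_qalys"]
print(f"MC median QALY gain     : {q.median:,.0f} (95% UI {q.p2_5:,.0f} to {q.p97_5:,.0f})")
```

prints

```
QALY gain over 10 years : 17,244
NHS savings             : £201.5 m
Social care savings     : £-38.3 m
Intervention cost (C_i) : £598.0 m
Classification          : icer
Cost per QALY           : £25,212
MC median QALY gain     : 17,243 (95% UI 17,180 to 17,323)
```

On this synthetic bundle the salt programme gains about 17,000 QALYs over
ten years and saves the NHS about £200 m; it is not outright cost saving
here because longer survival raises late-life social-care expenditure (a
negative "saving"), leaving a cost per QALY of about £25,000 — comfortably
under the usual £20,000–30,000 decision thresholds. The Monte Carlo
interval reflects only the declared effect-size uncertainty, which is small
at national diary sample sizes.

The same bundle supports the leisure-centre scenario
(`qs.build_leisure_scenario(...)`), lifetime horizons (`horizon=None`),
alternative discount rates, perspectives (`nhs_only`, `social_only`) and
an industry-cost toggle.

## Command line

```
qalysim generate --seed 1 --out bundle/
qalysim run-scenario --inputs bundle/ --scenario salt --out results/
qalysim run-mc --inputs bundle/ --scenario leisure --out mc/ --n 2000 --seed 1
qalysim sensitivity --inputs bundle/ --scenario salt --out sens/ --sweep horizon
```

Outputs are machine-readable (results JSON, by-sex CSV, trajectory CSVs,
cost-effectiveness plane CSV). Exit codes distinguish configuration errors
(2), input validation failures (3) and runtime errors (4).

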
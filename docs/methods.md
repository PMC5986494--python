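# Methods

This note documents the model implemented in `fopl_cea`: its structure,
assumptions, default parameters, numerical choices, and what the
synthetic data generator does and does not emulate.

## 1. Intervention effect size

The intervention is supply-side only: front-of-pack labelling is assumed
to change what manufacturers put in packages, not what consumers buy.
Consumers keep purchasing the same grams of each food category, so an
energy-density change passes through one-for-one into energy intake.

Per food category, the label-attributable effect is a
difference-in-difference on unweighted product means: the change
(post − pre) among products that displayed the label post-implementation
minus the change among products that did not. Arms are fixed by the
post-implementation label flag; products missing in either year are
dropped before analysis. Percentage changes are relative to each arm's
own baseline, so the DiD is in percentage points; the *absolute* DiD
(kJ/100 g) is what propagates downstream. A category with an empty arm
has an undefined DiD and contributes zero effect, with a logged warning.

The voluntary-scenario change in a category's average energy density is
the absolute DiD diluted by the category's labelled share; the mandatory
scenario removes the dilution by cross-multiplying each category's
voluntary change by 100%/uptake%. Scaling is per category because
uptake differs substantially across categories. An attributable-fraction
lever in [0, 1] scales all category effects for sensitivity analysis
(defaults to 1 — all observed reformulation attributed to the label).

Uptake gets a Wald (normal-approximation) binomial 95% interval, which
reproduces the published interval for 1004/14,986 exactly at 1 dp; the
labelled-arm energy-density change is tested with a standard two-sided
paired t-test.

## 2. Intake, weight and BMI

Cohorts are age-group × sex strata. Per cohort,

    Δe [kJ/day] = Σ_categories ΔED [kJ/g] × grams/day,

with kJ/100 g converted to kJ/g by ÷100 (stated explicitly because a
unit slip here is the most likely silent bug). A sustained intake change
maps to an eventual steady-state weight change Δkg = Δe/ρ. The
energy-balance literature gives a range of coefficients; the default
ρ = 100 kJ/day per kg (adults and children alike) is a deliberate
round-number approximation and a config parameter
(`EnergyWeightParams`). BMI change is Δkg/height² using the cohort's
mean height. The shift is treated as permanent and identical in every
cycle ("constant effects over time"); children get the same treatment
as adults, with no growth modelling — a documented simplification.
`shift_lognormal` refits lognormal parameters after a location shift of
the mean with the natural-scale SD preserved.

## 3. Proportional multi-state life table

Each cohort is followed annually from its 2010 starting age (taken as
the lower bound of its 5-year group) to age 100 or extinction. Input
rates are supplied per 5-year group and held constant within a group;
the engine expands them to single years of age — standard life-table
practice that keeps input tables small.

Each of the nine diseases runs as an independent three-state sub-model
per cohort (healthy / prevalent case / dead-of-disease, per capita),
with annual difference equations

    healthy' = healthy − i·healthy + r·cases
    cases'   = cases + i·healthy − r·cases − f·cases
    dead'    = dead + f·cases

which conserve persons exactly. Cohorts start disease-free; remission
defaults to 0 (no data source). Diseases are adult-onset (incidence 0
below the configurable minimum age, default 18), so BMI shifts in child
cohorts only bite once the cohort ages into adulthood.

The proportional step: in the intervention arm each disease's incidence
is multiplied by (1 − PIF). PIF applies to incidence only — not to
prevalence or case fatality — which is the standard proportional
life-table treatment for this model family. The intervention arm's
all-cause mortality is the background rate plus
Σ_d f_d·(prev_int − prev_comp), and its YLD rate is the background rate
plus Σ_d dw_d·(prev_int − prev_comp); both must stay in [0, 1) or the
run raises a model-consistency error. (An alternative bookkeeping that
builds total YLD from per-disease prevalent-YLD rates was considered
and not implemented; disability-weight adjustment of a background YLD
rate is the single supported mode.)

Person-years use start-of-cycle survivorship with no half-cycle
correction; HALY(t) = survivors(t) × (1 − YLD(t)) × (1 + r)^−t with
r = 3%/year and cycle 0 = 2010. With a one-cycle horizon and no
discounting this reduces exactly to survivors × (1 − YLD).

**PIF integration.** The expectation E[RR(B − d)] is computed on a fixed
2001-point linear grid spanning the central 99.99% of the cohort's
lognormal BMI mass, by trapezoidal integration of the lognormal pdf
(normalised over the grid, so truncation cancels in the ratio). RR is
floored at 1 at or below the reference BMI (default 21 kg/m²,
configurable) to avoid crediting reductions among people already below
the minimum-risk level. The grid estimate agrees with a 10⁶-draw Monte
Carlo simulation to well within simulation error (tested at 3 SE). The
cohort's *baseline* BMI distribution is used at every age — BMI is not
aged within a cohort — which is a homogeneity simplification of the
cohort model.

A consequence worth knowing: because the intervention arm keeps more
people alive, *absolute* prevalent case counts can rise even while
per-capita prevalence falls in every cohort-cycle; the monotone
invariants (and tests) are stated on prevalence rates and discounted
offsets, not raw case counts.

## 4. Costs, offsets and ICERs

Cost items carry schedules: `annual` (government administration and
monitoring, over the whole horizon), `per_cycle` (industry re-labelling,
default 3-year cycle), `one_off` (legislation, mandatory scenario only,
year 0). Occurrences are discounted at the model rate and summed. The
published lifetime cost totals are not derivable from the published
per-period items by any single schedule, so schedules are configuration,
the shipped default is an interpretation, and the acceptance checks use
the published totals as inputs to the net-cost identity rather than
deriving them.

Offsets are Σ cost_d × Δ(prevalent case-years), discounted; negative
values are savings. ICER = net cost / incremental HALYs; an intervention
that saves money and gains health is "dominant", one that costs money
and loses health is "dominated", zero incremental HALYs is reported as
an undefined ICER (flagged, not raised).

Under uncertainty the "mean ICER" is the mean of per-iteration ratios
over iterations with positive incremental HALYs, with cost-saving
iterations contributing their negative ratio. This per-iteration mean is
heavy-tailed (near-zero-effect iterations produce extreme ratios) —
which is precisely why it can sit far from the ratio of mean net cost to
mean HALYs; both are reported.

## 5. Probabilistic sensitivity analysis

2000 iterations by default (tests use 200). Per iteration, independent
draws of:

* **effect** — Normal with SD equal to the absolute mean weight change
  (the convention when no sampling variance is available; the
  `effect_sd_ratio` config generalises it). The draw rescales the whole
  per-cohort weight-change vector, preserving age/sex structure.
* **costs** — modified Pert (scaled Beta, λ = 4) over expert
  (min, mode, max); the legislation item uses a Gamma matched to its
  point estimate (mean) and range (SD = width/3.92).
* **relative risks** — lognormal on the log scale, with log-SD supplied
  per disease (derived in the generator from a synthetic 95% CI as
  log-width/3.92; the published SD recipe for RRs is ambiguous, so the
  parameterisation is explicit rather than claimed).
* **cohort mean BMI** — multiplicative lognormal with a 2% relative SE
  by default.

Draw independence across parameter blocks is assumed. One master seed;
iteration k uses substream `default_rng([seed, k])` so any iteration is
reproducible in isolation. Iterations that violate model consistency are
counted, not dropped. Quadrant shares classify (ΔHALY, net cost) signs
with boundary ties to the positive side (zero cost → North, zero HALYs
→ East); the ICER interval's lower bound is reported as "dominant" when
the 2.5th-percentile iteration is cost saving.

## 6. Synthetic data

The generator emulates the *structure* of the unavailable sources, not
their marginals:

* **products** (default 14,986) — category baselines log-spaced over
  ≈200–3000 kJ/100 g; product-level change noise SD 40 kJ/100 g; common
  secular drift −1 kJ/100 g; labelled products (Bernoulli 6.7%) get an
  extra mean change of −7.11 kJ/100 g (the published labelled-arm mean
  change), so the labelled-vs-unlabelled differential converges to that
  value by construction;
* **consumption** — packaged-food intake ramping to ~900 g/day in
  adults (+15% for males), split across categories by a shared Dirichlet
  share vector;
* **population** — 5-year groups 0–100 × sex; ~22m persons total;
  lognormal BMI with natural-scale means rising from ~16 (childhood) to
  ~28.5 (age 65), CV 0.17; stylised Gompertz mortality (monotone above
  age 10) and a YLD rate rising with age;
* **diseases** — nine anonymous adult-onset conditions (the published
  model names none), log-linear age-increasing incidence and case
  fatality, disability weights 0.05–0.35, RR per 5 BMI units 1.1–1.65,
  costs A$1.5–12k per prevalent case-year;
* **costs** — the published point values and expert ranges verbatim.

Seed 20100614 is the shipped reference fixture. What passing tests on
this fixture show is that the *machinery* is correct (arithmetic
identities, conservation, monotonicity, convergence to known oracles);
they do not show that the fixture's HALY or cost magnitudes match the
Australian population — those depend on the proprietary inputs, and the
fixture's stronger intake effect (≈−4.4 kJ/day voluntary) makes its
point estimates more favourable than the published ones.

## 7. Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| discount rate | 0.03 /year | costs and HALYs alike |
| WTP threshold | A$50,000 /HALY | cost-effectiveness judgement |
| horizon | age 100 | annual cycles from 2010 |
| ρ (energy balance) | 100 kJ/day per kg | adults = children; configurable |
| reference BMI | 21 kg/m² | RR floored at 1 below it |
| PIF grid | 2001 points, central 99.99% | trapezoidal |
| PSA iterations | 2000 | test suite uses 200 |
| labelling cycle | 3 years | industry cost recurrence |

The test suite runs the full fixture (40 cohorts × ≤100 cycles × 9
diseases) with a 200-iteration PSA; the acceptance script runs both
scenarios at the full 2000 iterations.

## 8. Known limitations

No demand-side behaviour; no nutrient-specific (sugar/sodium/saturated
fat) pathways; no comorbidity interactions or time trends in background
rates; cohort homogeneity within strata; baseline-BMI distributions are
not aged; cost schedules are an interpretation; the Wald uptake interval
and the SD-equals-mean effect distribution are conventions, not
estimates of real sampling variance.
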
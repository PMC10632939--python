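# Methods

## Model

The engine is a discrete-time Markov cohort model. The state at calendar
year *t* is a non-negative array of person counts over single years of age
0–84 plus an absorbing 85+ bin, sex, and seven smoking states: never
smoker, current smoker, and former smoker in five quit-duration categories
(1–2, 3–5, 6–10, 11–15, ≥16 years; the category set follows the
established simulation lineage for this class of models, which models
relapse risk as declining with time since quitting).

One simulated year applies, in order:

1. **Demography.** Each cohort ages one year with survival
   1 − m(a,s)·ρ(k), where m is the age–sex death probability and ρ(k) an
   optional relative-mortality factor by smoking state (1.0 by default for
   user-supplied rates). Births equal age-specific fertility applied to
   the whole female population and enter age 0 as never smokers, split by
   the sex ratio at birth.
2. **Smoking transitions.** Within each age–sex cohort, flows computed
   simultaneously from the pre-transition state: never→current by
   initiation (nonzero only in the window 15–24 by default),
   current→former(1–2) by cessation, former(d)→current by relapse(d).
   Non-relapsing former smokers advance one duration category per year at
   rate 1/width of their category. Transitions conserve cohort totals
   exactly.
3. **Policy stock adjustments.** Multiplicative one-off adjustments of the
   current-smoker stock (see below).

Adult prevalence is the population-weighted share of current smokers at
ages ≥19, reported in percent; the combined-sex figure weights the sexes
by their modeled adult populations.

## Policy module

Non-price components (smoke-free air P, cessation support O, warnings W,
advertising bans E) carry achieved effect fractions per implementation
level (packaged in `data/effects.yaml` and overridable). A level change
applies

* a **one-off prevalence multiplier** (1 − PE_new)/(1 − PE_old) to the
  current-smoker stock in the year of the change,
* a **persistent initiation multiplier** built the same way from the
  initiation effects, and
* a **persistent cessation multiplier** (1 + CE_new)/(1 + CE_old).

Components combine multiplicatively, which keeps combined effects below 1
and makes multi-step level changes path-independent. Venue effects within
the smoke-free-air component also combine multiplicatively; per the
effect-size convention, clean-air effects apply equally to prevalence,
initiation and cessation; cessation support has no initiation pathway; the
partial advertising ban has no cessation effect; enforcement/publicity
adds one percentage point to each pathway it accompanies. The partial
level of the bars/other venue (not separately tabulated) is encoded as
half its complete value, consistent with the "partial = 50%" treatment of
cessation support.

Price effects use age-banded elasticities of participation applied to the
proportional change in the real price between consecutive years:
prevalence and initiation multiply by max(floor, 1 + ε·ΔP/P) and cessation
by the reciprocal. Real prices deflate nominal prices by cumulative
inflation (3%/year from 2023, CPI base 2022). Recomputing from
consecutive real prices makes a sustained real increase a one-time level
effect that persists, while real-price erosion under a frozen nominal
price feeds back gradually. The floor (0.2) keeps probabilities valid
under extreme price paths. The linear elasticity form is antisymmetric
only to first order: a raise-then-restore cycle returns the combined
multiplier to 1 up to a second-order term (≈ε²·(ΔP/P)²).

**Displaced smokers.** A prevalence multiplier below 1 moves current
smokers into the *terminal* (≥16 years) former category rather than the
recent-quitter category. The one-off prevalence effects in this model
family represent settled population-level behaviour change, not fresh
individual quit attempts; routing them through the 1–2 year category
would expose them to ~12%/year relapse and erode the policy effect within
a decade, contrary to the persistent scenario gaps this model family
projects. A multiplier above 1 draws smokers back from the former
categories proportionally, capped by availability.

## Scenarios

Seven built-in scenarios run from a 2022 baseline to 2050, with policy
strengthening in one step at the start of 2023: the status quo (2022
levels held: partial clean air, partial cessation support, strong
warnings without extra enforcement, partial advertising ban, KRW 4500
nominal price); full non-price strengthening (POWE: complete clean air,
full cessation support, warnings with enforcement/publicity,
comprehensive advertising ban with enforcement); price jumps to KRW 8000
with optional 10% annual nominal growth; and a tobacco-free generation
(TFG) ban with cutoff birth year 2003, implemented as exactly zero
initiation for ages a with year − a > 2003 from 2023 ("born after 2003",
i.e. birth year ≥ 2004). Projections are deterministic given inputs.

## Synthetic baseline and calibration

The measured inputs behind the original projection are unpublished, so a
generator produces a stylized stand-in:

* **Population**: birth cohorts shrinking 1.2%/year over the last 45
  years (below-replacement fertility, TFR 1.05, maternal ages ~18–45
  peaked at 32; sex ratio at birth 0.515), survived through Gompertz-like
  mortality (m(a) = c₀ + c₁·e^{0.095a}, male above female).
* **Smoking schedules**: triangular initiation on ages 15–24 with free
  peak age and sex-specific scales; cessation 0.012 + 0.0010·(a − 40)₊
  scaled per sex — quitting accelerates from midlife, which yields the
  hump-shaped prevalence-by-age cross-section seen in surveys; relapse
  declining with quit duration (0.12, 0.06, 0.03, 0.015, 0.005 × free
  scale).
* **Differential mortality**: current smokers carry a relative all-cause
  mortality of 1.5 versus never smokers in the generated baseline, with
  the excess fading linearly with quit duration. This selective loss of
  older smokers is a standard feature of this model family and is needed
  for realistic old-age prevalence; the engine default for user-supplied
  rates remains 1.0.
* **2022 state**: each cohort's smoking-state mix is the outcome of
  simulating that cohort from birth through the schedules, with a
  cohort-specific historical elevation of initiation ramping up over
  current ages 45–68 (the uptake epidemic peaked in cohorts now past
  midlife). The elevation factor κ is solved per sex (Brent's method) so
  that 2022 adult prevalence matches the anchors exactly (male 35.3%,
  female 3.6%). The same construction gives the status-quo projection its
  decelerating decline: elevated older cohorts die and quit out of the
  population while younger cohorts are near their dynamic equilibrium.

Calibration adjusts six parameters (initiation scale ×2, cessation scale
×2, initiation peak age, relapse scale) by Nelder–Mead in transformed
(log-scale) coordinates with one restart (default budget 700–1200
evaluations, deterministic), minimizing the equally-weighted sum of
squared deviations (%p²) at the twelve status-quo anchor points
(2025–2050, both sexes). Typical fits reach loss ≈ 0.12 (%p)² with a
maximum anchor deviation of ≈ 0.25 %p. The target band is loss ≤ 0.5;
results above it are flagged `converged=False`, not raised, and fits with
fewer anchors than parameters are flagged under-determined.

**Identifiability.** The status-quo path constrains the *combination* of
cessation and relapse (net quitting) much more strongly than either
separately; parameter-recovery experiments recover initiation scales and
peak age essentially exactly (loss < 10⁻⁴), while cessation and relapse
scales can trade off along a ridge with little loss penalty. The female
trajectory is calibrated exactly as printed even though the underlying
model family is known to track female smoking less well; this caveat is
inherited, not corrected.

## Sensitivity analyses

* **One-way**: every effect size of one MPOWER component (elasticities
  for R) is scaled by 1 + δ, δ ∈ {−0.5, −0.25, 0, +0.25, +0.5} (fractions
  clipped to [0, 0.95]), and the combined endgame scenario is rerun; the
  grid reports prevalence at 2030 and 2050 by sex and total. Prevalence
  responds monotonically to δ for every component and is dominated by the
  price component. Note: because the perturbation scales the whole effect
  family — including the cessation-rate increase of the
  cessation-support component — the O row is *not* numerically flat here
  (max ≈ 0.4 %p); a perfectly flat O row would require the O parameters
  not to participate in the scenario at all, which would contradict their
  role in the non-price package.
* **Probabilistic**: each policy family receives an independent scale
  factor drawn from Beta(7.5, 7.5) rescaled to [0.5, 1.5] (mean 1,
  SD 0.125; shape configurable — the original distributional settings are
  not published), the scenario is rerun per draw (default 1000), and 95%
  intervals use the bias-corrected percentile method: z₀ = Φ⁻¹(share of
  draws below the point estimate), endpoints at the empirical quantiles
  Φ(2z₀ ± 1.959964). With exactly half the draws below the point this
  reduces to the plain percentile interval; if all draws fall on one side
  the plain interval is returned with a warning. The draws are parametric
  Monte-Carlo draws of the policy parameters — there is no data to
  resample.

## Numerical choices and conventions

* All internal arithmetic is in full double precision; reported tables
  round half-up to one decimal.
* Calendar years are closed integers; ages are completed years.
* Quit-duration progression uses the 1/width-per-year approximation
  rather than tracking single years of quit duration.
* The 1995–2022 tracking period of the original analysis is replaced by
  direct initialization at the calibrated 2022 state.
* Problem sizes: the synthetic population holds ≈ 76,000 fractional
  persons (1000-per-birth-cohort scale — counts are continuous, so scale
  only sets readability); the agent-based cross-check uses 10⁵ agents;
  test-suite sensitivity runs use reduced draw counts (30–200) against
  the 1000-draw default.

## What the synthetic baseline does and does not show

The generator reproduces the published starting prevalences exactly and
the status-quo trajectories within 0.3 %p, and the policy deltas then
follow largely from the published effect sizes. It does not reproduce
Korea's true age pyramid, migration (excluded), real initiation/cessation
schedules, other tobacco products (excluded), or survey-calibrated
female smoking behaviour. Passing tests demonstrate internal consistency
and faithful policy arithmetic on a plausible baseline — not validation
against real survey series, for which a comparator hook
(`compare_to_survey`) is provided but no survey data are bundled.
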
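# Policy effect sizes by MPOWER component, and age-banded price elasticities.
# All non-price entries are achieved fractional effects on smoking prevalence,
# initiation, and/or cessation at the stated implementation level.
# Values may be overridden by loading a modified copy of this file.
version: 1
clean_air:
  # fractional prevalence reduction by venue and level; per the effect-size
  # convention, clean-air effects apply equally to prevalence, initiation
  # and cessation.  The partial bars/other value is half the complete one.
  workplace: {complete: 0.06, partial: 0.02}
  restaurant: {complete: 0.01, partial: 0.005}
  bars_other: {complete: 0.005, partial: 0.0025}
cessation_treatment:
  # high-intensity support: prevalence reduced 2.6%, cessation rate +50%;
  # partial implementation scales both by partial_fraction
  prevalence_reduction: 0.026
  cessation_rate_increase: 0.50
  partial_fraction: 0.5
warnings:
  high: {prevalence: 0.02, initiation: 0.02, cessation: 0.04}
  low: {prevalence: 0.01, initiation: 0.01, cessation: 0.02}
  enforcement_publicity: 0.01
ad_ban:
  comprehensive: {prevalence: 0.06, initiation: 0.08, cessation: 0.03}
  complete: {prevalence: 0.04, initiation: 0.06, cessation: 0.02}
  partial: {prevalence: 0.01, initiation: 0.01, cessation: 0.0}
  enforcement_publicity: 0.01
price_elasticity:
  # proportional change in smoking per proportional change in real price
  age_15_17: -0.4
  age_18_24: -0.3
  age_25_34: -0.2
  age_35_plus: -0.1
# lower bound on any price-derived prevalence/initiation multiplier, keeping
# probabilities valid under extreme price paths
multiplier_floor: 0.2
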
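# High mobile-penetration setting: near-universal ownership in every
# stratum, mild gradients only.  Weighting has little to correct and both
# survey arms should sit near a design effect of 1.
name: scenario_b
total_n: 600
seed: 0
population:
  dimensions: [residence, age_band]
  strata:
    - {levels: [urban, 18-39], size: 5000, ownership: 0.99, prevalence: 0.15,
       answer_propensity: 0.85}
    - {levels: [urban, 40-59], size: 3000, ownership: 0.97, prevalence: 0.25,
       answer_propensity: 0.80}
    - {levels: [urban, 60-70], size: 1000, ownership: 0.90, prevalence: 0.40,
       answer_propensity: 0.75}
    - {levels: [rural, 18-39], size: 6000, ownership: 0.95, prevalence: 0.20,
       answer_propensity: 0.80}
    - {levels: [rural, 40-59], size: 4000, ownership: 0.92, prevalence: 0.30,
       answer_propensity: 0.75}
    - {levels: [rural, 60-70], size: 1000, ownership: 0.85, prevalence: 0.45,
       answer_propensity: 0.70}
frame:
  plans:
    - {prefix: "017", suffix_length: 7, market_share: 0.6}
    - {prefix: "019", suffix_length: 7, market_share: 0.4}
  nonworking_fraction: 0.2
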
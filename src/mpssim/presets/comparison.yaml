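# Heterogeneous-ownership scenario for the AASM vs unrestricted-RDD
# head-to-head: ownership and answer propensity fall along the urban/rural
# and age gradients, so an unrestricted RDD sample over-represents young
# urban owners and needs variable poststratification weights, while the
# quota arm fills every cell to its census share.
name: comparison
total_n: 1000
seed: 0
population:
  dimensions: [residence, age_band]
  phone_counts: {1: 0.85, 2: 0.10, 3: 0.05}
  strata:
    - {levels: [urban, 18-39], size: 12500, ownership: 0.95, prevalence: 0.15,
       answer_propensity: 0.90, response_propensity: 0.85}
    - {levels: [urban, 40plus], size: 12500, ownership: 0.80, prevalence: 0.25,
       answer_propensity: 0.70, response_propensity: 0.85}
    - {levels: [rural, 18-39], size: 12500, ownership: 0.50, prevalence: 0.30,
       answer_propensity: 0.50, response_propensity: 0.85}
    - {levels: [rural, 40plus], size: 12500, ownership: 0.30, prevalence: 0.45,
       answer_propensity: 0.30, response_propensity: 0.85}
frame:
  plans:
    - {prefix: "017", suffix_length: 7, market_share: 0.6}
    - {prefix: "019", suffix_length: 7, market_share: 0.4}
  nonworking_fraction: 0.2
  pool_factor: 10
dialer:
  max_redials: 3
  operator_feedback: true
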
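# Low mobile-penetration setting: ownership collapses with age and outside
# towns, leaving the oldest strata nearly unreachable by phone.  Quotas for
# those cells depend on the stopping rules; the run demonstrates abandonment
# rather than full quota attainment.
name: scenario_a
total_n: 400
seed: 0
population:
  dimensions: [residence, age_band]
  strata:
    - {levels: [urban, 18-39], size: 5000, ownership: 0.60, prevalence: 0.15,
       answer_propensity: 0.80}
    - {levels: [urban, 40-59], size: 3000, ownership: 0.35, prevalence: 0.25,
       answer_propensity: 0.70}
    - {levels: [urban, 60-70], size: 1000, ownership: 0.05, prevalence: 0.40,
       answer_propensity: 0.60}
    - {levels: [rural, 18-39], size: 6000, ownership: 0.25, prevalence: 0.20,
       answer_propensity: 0.60}
    - {levels: [rural, 40-59], size: 4000, ownership: 0.10, prevalence: 0.30,
       answer_propensity: 0.50}
    - {levels: [rural, 60-70], size: 1000, ownership: 0.02, prevalence: 0.45,
       answer_propensity: 0.40}
frame:
  plans:
    - {prefix: "017", suffix_length: 7, market_share: 0.6}
    - {prefix: "019", suffix_length: 7, market_share: 0.4}
  nonworking_fraction: 0.4
aasm:
  stopping: {effort_factor: 25.0}
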
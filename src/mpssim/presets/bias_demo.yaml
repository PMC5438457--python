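# Differential-ownership scenario for the bias-removal demonstration:
# urban residents own (often several) phones and answer readily, rural
# residents own fewer phones and rarely pick up, and the outcome prevalence
# differs sharply between the two.  An unweighted RDD sample is dominated by
# urban respondents; poststratification to the phone-owner strata
# distribution restores the owner-population mix.
name: bias_demo
total_n: 5000
seed: 0
population:
  dimensions: [residence]
  strata:
    - {levels: [urban], size: 30000, ownership: 0.90, prevalence: 0.20,
       answer_propensity: 0.90, response_propensity: 1.0,
       phone_counts: {1: 0.60, 2: 0.25, 3: 0.15}}
    - {levels: [rural], size: 30000, ownership: 0.45, prevalence: 0.50,
       answer_propensity: 0.15, response_propensity: 1.0,
       phone_counts: {1: 1.0}}
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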
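# Multi-phone ownership preset: everyone owns a phone, 10% own three.
# Mirrors the 90%/10% row of the closed-form inclusion-probability table at
# simulator scale, for measuring the 3x contact-rate advantage empirically.
name: table2_10pct
total_n: 500
seed: 0
population:
  dimensions: [group]
  phone_counts: {1: 0.90, 3: 0.10}
  strata:
    - {levels: [all], size: 10000, ownership: 1.0, prevalence: 0.30,
       answer_propensity: 1.0, response_propensity: 1.0}
frame:
  plans:
    - {prefix: "017", suffix_length: 7, market_share: 1.0}
  nonworking_fraction: 0.0
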
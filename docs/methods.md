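# Methods

## The model in brief

`mpssim` simulates a cross-sectional mobile phone survey (MPS) run by random
digit dialing (RDD) against a synthetic population, with an optional
real-time quota engine (automated active strata monitoring, AASM), and then
applies the standard post-survey weighting stack. The pipeline is

    population  →  frame  →  dialer  →  aasm  →  weights

with an `experiment` layer that runs the whole chain twice — quota engine on
(AASM) and off (unrestricted RDD) — on the same population and the same
initial number frame, so that active strata monitoring is the only
difference between the two arms.

### Population

A population is a fixed cross-section partitioned into demographic strata
(a Cartesian product of declared dimensions; the shipped presets use
residence × age band). Per-stratum **sizes are exact** (deterministic
allocation), while everything else is stochastic given the seed:

* phone ownership: Bernoulli per person with a per-stratum probability;
* phones per owner `T_i`: drawn from a per-stratum (or global) categorical
  distribution over {1, 2, 3, …};
* a binary outcome with per-stratum prevalence — the estimand is a
  prevalence, in keeping with the package's target use (risk-factor
  surveillance);
* answer and response propensities, constant within a stratum.

Exact sizes make the census-style `ReferenceDistribution` exact by
construction, so quota targets and poststratification factors are not
contaminated by generator noise; the sampling noise lives where a survey
actually meets it (ownership, answering, responding).

Assumptions worth stating: within a stratum, ownership, answering and the
outcome are independent; propensities are homogeneous within strata; there
is no panel/longitudinal structure and no geography beyond the declared
dimensions. Shared handsets are modeled only as "non-primary users answer
only in the evening" — a minimal mechanism for time-of-day targeting, not a
behavioural model. Households exist only to support snowball referral and
default to size 1 (mechanism off).

### Frame

Candidate numbers are generated inside each operator's prefix block,
apportioned to operators by **largest-remainder rounding** of market shares
(exact, deterministic — ties broken by declaration order), and unique
across every batch ever drawn in a run. A configurable fraction *Y* of each
batch is nonworking.

Two deliberate numerical choices:

* **Exact batch composition.** Each batch of *m* numbers contains exactly
  `round(m·(1−Y))` working numbers (fewer only if the population's phone
  slots run out); which numbers are working, and whose phone each rings, is
  random. This mirrors the population module's exact-sizes choice and makes
  the 1/(1−*Y*) sample-size inflation exactly conservative: dialing
  `ceil(n/(1−Y))` numbers yields at least *n* working contacts in
  expectation with no knife-edge dependence on binomial luck.
* **Slot linkage.** A person owning *T* phones holds *T* "slots"; working
  numbers are dealt to a random permutation of all slots without
  replacement. Selection probability is therefore proportional to phones
  owned by construction — the property the 1/*T* weight adjustment undoes —
  and no person can own more working numbers than phones.

The nonworking fraction used for inflation can either be read from config
or estimated from a practice round on a test pool (share of resolved
numbers that were nonworking, with its binomial standard error); the
estimator counts only resolved outcomes, leaving unresolved numbers to the
dialer's own write-off rule.

### Dialer and replacement

Each call attempt resolves one number: nonworking numbers return an
operator invalid-number signal (configurable; where the network provides
none they simply ring out), working numbers are answered with the owner's
propensity modulated by the time-of-day slot (slots drawn i.i.d. from
configured weights). Answered calls flow through refusal → stratum
screening → quota decision → possible mid-interview dropout → completion;
the order of the three questionnaire modules is randomized per completed
interview and recorded.

Replacement bookkeeping ("accelerated sequential replacement"): a number
still unresolved after `max_redials` redials (default 3 — the limit is a
design parameter, not an estimate) is written off as nonworking; at stage
end (or immediately, in automated mode) every verified-nonworking number is
replaced one-for-one with a fresh unique number. Because answered numbers
retire as verified households without replacement, an active pool depletes;
the runner draws a fresh pool from the reserve whenever the live count
falls below the inflated sample size, which is the "generate a new pool if
depleted" rule.

**Close-out rule (our extension):** when the survey stops (quotas met,
ceiling hit), numbers still mid-resolution are written off as nonworking
and replaced one final time. This extends the redial write-off rule to
survey termination so that every generated number ends in exactly one of
three terminal states — verified household, verified nonworking, or
never-dialed surplus — and the count of replacements equals the count of
verified-nonworking numbers, an invariant the test suite audits.

Refusals are terminal for the number (no callback) and are recorded with
the refuser's true stratum — simulation ground truth standing in for the
external estimation a real survey would need for group nonresponse rates.

### Quota engine (AASM)

Targets are the census reference shares times the total sample size,
rounded by largest remainder so they sum exactly. Screening increments a
per-stratum effort counter; admission requires the stratum to be open;
**only completed interviews fill quota** (dropouts do not); a stratum
closes exactly at its target and never reopens; no person is interviewed
twice (sampling without replacement), even when a second of their phones is
reached. Stopping rules abandon an open stratum once screened arrivals
exceed `effort_factor × target` (default 50 — the engine's patience before
declaring a cell unreachable), or every open stratum once a global call
ceiling is hit (default 100 × total_n). A configured run with a
zero-ownership stratum and the stopping rules disabled is refused up front,
since it cannot terminate. Snowball referral, when enabled, asks a
completed or excused respondent to hand the phone to a household member
from a still-open stratum, succeeding with a configured probability; the
referred interview is flagged in the call log.

### Weights

The final weight composes multiplicatively: base (1 under equal-probability
RDD) × poststratification `P_h/p_h` × nonresponse `R = 1/(1−f)` ×
multi-phone `A = 1/T` (× a trim factor if trimming is applied). Order is
immaterial for a product; the factors are kept separately in the exported
`WeightSet` so each adjustment is auditable.

* The nonresponse factor's functional form is the standard inverse response
  rate; we compute per-stratum `f` as (refusals + dropouts)/(refusals +
  dropouts + completions). This inverse-complement form is an
  interpretation of the usual group-level nonresponse correction, flagged
  as such.
* CV of weights uses the **population (divide-by-n) standard deviation**
  over the mean; with that convention Kish's `deff = 1 + CV²` is
  *algebraically identical* to `n·Σw²/(Σw)²`, and the suite property-tests
  the identity to 1e-12. The reported variance of a weighted estimate is
  the SRS variance times this deff — Kish's approximation, reported as
  such; no replication variance (jackknife/bootstrap) is implemented.
* Trimming clips to [lower, upper] then rescales to preserve the weight
  total; it can only reduce the CV, and any bias it introduces is the
  user's trade to make.
* Weight normalization (mean 1) is cosmetic: every reported diagnostic is
  scale-invariant.

Closed-form selection probabilities `(n·N_p)/N_T` are exposed directly and
through the inclusion-probability table for the 100-million-owner grid;
printed values are rounded half-away-from-zero on the shortest decimal
representation (so 1.875e-8 prints as 1.88e-8, as it would by hand).

### Calibration targets: which mean does weighting recover?

Poststratification calibrates the sampled strata composition to whatever
reference it is given; which *population* mean that recovers depends on the
reference:

* calibrating to the **phone-owner strata distribution**
  (`reference_distribution(pop, owners_only=True)`; in the field,
  census/DHS ownership margins) recovers the phone-owner population mean —
  this is the bias-removal property the `bias_demo` scenario demonstrates,
  where differential answer propensities and multi-phone ownership skew
  the unweighted RDD sample far off the owner mix;
* calibrating to the **full census distribution** (what the quota targets
  use) targets the census-weighted mixture of *owner* stratum means, which
  still differs from the full-population mean wherever owners and
  non-owners differ. That residual coverage bias is not removable by any
  within-frame weighting; the comparison report therefore prints biases
  against both the owner-population and the full-population truths rather
  than asserting the latter away. The `ownership_gap_report` quantifies the
  gap at its source.

## Study conditions and problem sizes

The shipped presets are the package's fixed study conditions:

* `comparison` — 4 strata × 12,500 people, ownership 0.95/0.80/0.50/0.30,
  answer propensities 0.90/0.70/0.50/0.30, Y = 0.2, 1,000 completions per
  arm. Used for the AASM-vs-RDD head-to-head.
* `bias_demo` — 2 strata × 30,000, urban (ownership 0.90, multi-phone mix,
  answer 0.90, prevalence 0.20) vs rural (ownership 0.45, single phones,
  answer 0.15, prevalence 0.50), 5,000 completions. Used for the
  bias-removal demonstration.
* `scenario_a` / `scenario_b` — illustrative low- and high-penetration
  settings (the penetration curves are schematic in the source setting, so
  these defaults are illustrative, not calibrated).
* `table2_10pct` — single stratum, 90% one-phone / 10% three-phone owners.

Monte-Carlo checks run at: 10⁵ dials for the contact-rate ratio (3.0 within
3 MC SEs), 1,000 replicates for the inflation calibration (n = 200,
Y = 0.5), 1,000 random weight vectors for the Kish identity. These sizes
give the assertions comfortable margins (the contact-ratio SE is ≈ 0.02;
the bias-demo design bias is ≈ 14 unweighted SEs) while keeping the whole
suite around ten seconds.

## Reproducibility

Every run is driven by one master seed; each pipeline stage (population,
frame, dialer, test pool) draws from its own named substream derived from
it, so toggling one stage does not perturb another's draws, and both
experiment arms see identical populations and initial frames. Two runs from
the same config and seed produce byte-identical reports.

## Known limitations

* No geographic coordinates, mobility or geolocation screening; no
  questionnaire content or skip logic; no telephony protocol, SMS/IVR,
  caller-ID, consent or incentive modeling; no cost/time accounting.
* No list-assisted or multiple-frame designs — RDD only.
* Quotas are fixed at launch; there is no mid-survey re-allocation, and
  closed strata never reopen (so whether excused respondents could be
  re-contacted never arises).
* Variance estimation is the Kish approximation only; no raking/IPF on
  multiple margins; no small-area estimation.
* Synthetic populations are homogeneous within strata; real ownership,
  answering and outcome gradients are continuous and correlated in ways the
  generator does not emulate — passing tests show the machinery is correct
  under the stated model, not that any particular field survey will achieve
  these design effects.
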
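"""End-to-end scenario runner: population -> frame -> dialer -> quota -> weights.

``run_scenario`` executes the same synthetic survey twice — once with the
quota engine enforcing census-proportional strata targets (AASM), once as
unrestricted RDD admitting every screened respondent — on the same
population and the same initial number frame, isolating active strata
monitoring as the only difference between arms.  The comparison report
carries each arm's achieved strata composition, weight CV, Kish design
effect, effective sample size, estimates and biases against both the
phone-owner and the full-population ground truths.

Also here: the closed-form inclusion-probability table for multi-phone
ownership, and small calibration experiments (contact rate proportional to
phones owned; sample-size inflation by 1/(1-Y)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import aasm as aasm_mod
from . import dialer as dialer_mod
from . import frame as frame_mod
from . import weights as weights_mod
from ._util import round_sig, substream
from .config import ScenarioConfig
from .population import (Population, StratumKey, generate_population,
                         reference_distribution)

# ---------------------------------------------------------------------------
# closed-form inclusion probabilities for multi-phone ownership

#: (share owning one phone, share owning three) grid used in the published
#: illustration for a population of 100 million phone owners
DEFAULT_TABLE2_GRID = ((1.0, 0.0), (0.9, 0.1), (0.8, 0.2),
                       (0.7, 0.3), (0.6, 0.4), (0.5, 0.5))


def table2(population_size: int = 100_000_000,
           grid=DEFAULT_TABLE2_GRID, sample_n: int = 1) -> pd.DataFrame:
    """Individual inclusion probabilities as multi-phone ownership grows.

    For each (share with 1 phone, share with 3 phones) row: the phone counts
    in each group, the per-person inclusion probability of a one-phone and a
    three-phone owner (to 3 significant figures), and their ratio, which is
    identically 3.
    """
    rows = []
    for p1, p3 in grid:
        if abs(p1 + p3 - 1.0) > 1e-9:
            raise ValueError(f"ownership shares {p1}+{p3} do not sum to 1")
        phones_one = int(round(population_size * p1))
        phones_three = int(round(population_size * p3 * 3))
        total = phones_one + phones_three
        s1 = weights_mod.SelectionScenario(sample_n, 1, total)
        s3 = weights_mod.SelectionScenario(sample_n, 3, total)
        rows.append({
            "pct_one_phone": p1, "phones_one": phones_one,
            "p_inclusion_one": round_sig(weights_mod.selection_probability(s1), 3),
            "pct_three_phones": p3, "phones_three": phones_three,
            "p_inclusion_three": round_sig(weights_mod.selection_probability(s3), 3),
            "relative_probability": weights_mod.relative_probability(s3, s1),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration experiments

def contact_rate_experiment(seed: int, n_dials: int = 100_000,
                            pct_three: float = 0.10,
                            population_size: int = 10_000) -> Dict[str, float]:
    """Measure the contact-rate advantage of multi-phone owners under RDD.

    A population where ``pct_three`` of people own three phones (the rest
    one) is fully covered by working numbers; ``n_dials`` uniform random
    dials are landed and contacts tallied per person.  Returns the empirical
    ratio of mean contacts (three-phone vs one-phone owners), which should
    be 3, with its delta-method Monte-Carlo standard error.
    """
    rng = substream(seed, "contact-rate")
    n3 = int(round(population_size * pct_three))
    n1 = population_size - n3
    phones = np.concatenate([np.ones(n1, dtype=np.int64), np.full(n3, 3, dtype=np.int64)])
    owners_of_slot = np.repeat(np.arange(population_size), phones)
    dial_slots = rng.integers(0, owners_of_slot.size, size=n_dials)
    contacts = np.bincount(owners_of_slot[dial_slots], minlength=population_size)
    c1, c3 = contacts[:n1], contacts[n1:]
    m1, m3 = c1.mean(), c3.mean()
    ratio = m3 / m1
    se = ratio * np.sqrt(c3.var(ddof=1) / (n3 * m3 ** 2) + c1.var(ddof=1) / (n1 * m1 ** 2))
    return {"ratio": float(ratio), "se": float(se),
            "mean_contacts_one": float(m1), "mean_contacts_three": float(m3),
            "n_dials": n_dials}


def inflation_calibration(seed: int, target_n: int = 200,
                          nonworking_fraction: float = 0.5,
                          replicates: int = 1000) -> Dict[str, float]:
    """Dial ceil(n/(1-Y)) generated numbers per replicate and count working
    contacts; reports the mean and the fraction of replicates reaching n."""
    rng = substream(seed, "inflation")
    inflated = frame_mod.inflate_sample_size(target_n, nonworking_fraction)
    plans = [frame_mod.MnoPlan("017", 7, 1.0)]
    working_counts = np.empty(replicates)
    pop = _uniform_population(size=2 * inflated, rng=rng)
    for r in range(replicates):
        pool = frame_mod.build_number_pool(plans, inflated, rng, population=pop,
                                           nonworking_fraction=nonworking_fraction)
        working_counts[r] = sum(num.working for num in pool)
    return {"inflated_n": inflated,
            "mean_working": float(working_counts.mean()),
            "fraction_reaching_target": float((working_counts >= target_n).mean()),
            "replicates": replicates}


def bias_removal_experiment(config: ScenarioConfig, seed: int) -> Dict[str, float]:
    """Poststratification bias removal on a differential-ownership scenario.

    Runs the unrestricted-RDD arm, then compares the unweighted prevalence
    estimate and the estimate poststratified to the phone-owner strata
    distribution (the calibration target for the reachable population)
    against the owner-population truth; the bias against the full-population
    truth — which includes non-owners no phone survey can reach and no
    weighting can recover — is reported alongside.
    """
    arm = run_arm(config, quota_enabled=False, seed=seed)
    pop = generate_population(config.population, substream(seed, "population"))
    owner_ref = reference_distribution(pop, owners_only=True)
    resp = [(r.respondent_id, r.stratum) for r in arm.records
            if r.outcome == dialer_mod.ANSWERED_COMPLETE]
    ids = np.array([i for i, _ in resp])
    strata = [k for _, k in resp]
    ws = weights_mod.poststratification_weights(strata, owner_ref, respondent_ids=ids)
    est = weights_mod.weighted_estimate(pop.outcome[ids], ws)
    unweighted = float(pop.outcome[ids].mean())
    owner_truth = pop.mean_outcome(owners_only=True)
    full_truth = pop.mean_outcome()
    n = len(ids)
    p = unweighted
    se_unweighted = (p * (1 - p) / n) ** 0.5
    return {
        "n": n,
        "owner_truth": owner_truth,
        "full_truth": full_truth,
        "estimate_unweighted": unweighted,
        "estimate_poststrat": est.estimate,
        "se_unweighted": se_unweighted,
        "se_poststrat": est.se,
        "bias_unweighted_owner": unweighted - owner_truth,
        "bias_poststrat_owner": est.estimate - owner_truth,
        "bias_poststrat_full": est.estimate - full_truth,
        "deff_poststrat": est.deff,
    }


def _uniform_population(size: int, rng) -> Population:
    """Minimal single-stratum population where everyone owns one phone."""
    from .config import PopulationConfig, StratumConfig
    cfg = PopulationConfig(
        dimensions=("all",),
        strata=[StratumConfig(levels=("all",), size=size, ownership=1.0,
                              prevalence=0.5, answer_propensity=1.0,
                              response_propensity=1.0)],
        phone_counts={1: 1.0})
    return generate_population(cfg, rng)


# ---------------------------------------------------------------------------
# the head-to-head survey arms

@dataclass
class ArmResult:
    """Everything one survey arm produced."""

    name: str
    completions: int
    calls: int
    stages: int
    numbers_generated: int
    replacements: int
    targets: Dict[StratumKey, int]
    achieved: Dict[StratumKey, int]
    estimate_unweighted: float
    estimate_poststrat: float
    estimate_final: float
    se_final: float
    cv_wt: float
    deff_wt: float
    effective_n: float
    bias_owner: float
    bias_full: float
    nonworking_fraction_used: float
    audit: Dict[str, int]
    weight_set: weights_mod.WeightSet = field(repr=False)
    records: List[dialer_mod.CallRecord] = field(repr=False)
    strata_table: pd.DataFrame = field(repr=False)

    def summary(self) -> Dict:
        return {
            "name": self.name, "completions": self.completions,
            "calls": self.calls, "stages": self.stages,
            "numbers_generated": self.numbers_generated,
            "replacements": self.replacements,
            "achieved": {"|".join(k): v for k, v in sorted(self.achieved.items())},
            "targets": {"|".join(k): v for k, v in sorted(self.targets.items())},
            "estimate_unweighted": self.estimate_unweighted,
            "estimate_poststrat": self.estimate_poststrat,
            "estimate_final": self.estimate_final,
            "se_final": self.se_final,
            "cv_wt": self.cv_wt, "deff_wt": self.deff_wt,
            "effective_n": self.effective_n,
            "bias_owner": self.bias_owner, "bias_full": self.bias_full,
            "nonworking_fraction_used": self.nonworking_fraction_used,
            "audit": self.audit,
        }


@dataclass
class ComparisonReport:
    """AASM vs unrestricted RDD on the same population and frame seeds."""

    config_name: str
    seed: int
    owner_truth: float
    full_truth: float
    aasm: ArmResult
    rdd: ArmResult

    def to_dict(self) -> Dict:
        return {"config_name": self.config_name, "seed": self.seed,
                "owner_truth": self.owner_truth, "full_truth": self.full_truth,
                "aasm": self.aasm.summary(), "rdd": self.rdd.summary()}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def probe_test_pool(pool, population: Population, config, rng) -> List[str]:
    """Practice RDD round: resolve each test number fully and return statuses.

    Working numbers are redialed until answered or written off; the answered
    interview itself is not conducted.
    """
    statuses = []
    for num in pool:
        status = frame_mod.UNRESOLVED
        for _ in range(config.max_redials + 1):
            if not num.working:
                if config.operator_feedback:
                    status = frame_mod.VERIFIED_NONWORKING
                    break
                continue
            person = population.person(num.owner_id)
            if rng.random() < person.answer_propensity:
                status = frame_mod.VERIFIED_HOUSEHOLD
                break
        if status == frame_mod.UNRESOLVED:
            status = frame_mod.VERIFIED_NONWORKING  # written off past the limit
        statuses.append(status)
    return statuses


def run_arm(config: ScenarioConfig, quota_enabled: bool,
            seed: Optional[int] = None, log=None) -> ArmResult:
    """Run one survey arm to its stopping condition."""
    master = config.seed if seed is None else seed
    pop = generate_population(config.population, substream(master, "population"))
    ref = reference_distribution(pop)
    frame_rng = substream(master, "frame")
    dial_rng = substream(master, "dialer")

    y_true = config.frame.nonworking_fraction
    plans = [frame_mod.MnoPlan.from_config(p) for p in config.frame.plans]
    frame = frame_mod.NumberFrame(plans, frame_rng, population=pop,
                                  nonworking_fraction=y_true)

    if config.frame.estimate_y:
        test_pool = frame.new_batch(config.frame.test_pool_size)
        statuses = probe_test_pool(test_pool, pop, config.dialer,
                                   substream(master, "test-pool"))
        y_used, _ = frame_mod.estimate_nonworking_fraction(statuses)
        y_used = min(y_used, 0.99)
    else:
        y_used = y_true

    inflated = frame_mod.inflate_sample_size(config.total_n, y_used)
    reserve_pool = frame.new_batch(config.frame.pool_factor * inflated)
    reserve = frame_mod.Reserve(frame, reserve_pool, batch_size=inflated)
    active = reserve.draw(inflated)

    plan = aasm_mod.make_quota_plan(ref, config.total_n) if quota_enabled else None
    engine = aasm_mod.QuotaEngine(plan, config.total_n,
                                  stopping=config.aasm.stopping,
                                  snowball=config.aasm.snowball, log=log)
    ceiling = config.aasm.stopping.global_call_ceiling or 100 * config.total_n

    records: List[dialer_mod.CallRecord] = []
    replacements = 0
    stage = 0
    while not engine.done:
        recs, in_stage = dialer_mod.run_stage(
            active, pop, config.dialer, engine, dial_rng, stage,
            reserve=reserve, call_ceiling=ceiling)
        records.extend(recs)
        replacements += in_stage
        replacements += dialer_mod.sequential_replacement(
            active, reserve, config.dialer.max_redials)
        stage += 1
        engine.apply_stopping(ceiling)
        if engine.done:
            break
        if engine.calls >= ceiling:
            # ceiling hit: abandon whatever is still open and stop
            engine.apply_stopping(engine.calls)
            break
        # a pool depletes as answered numbers become verified households;
        # draw a fresh pool so dialing can continue until quotas resolve
        live = sum(n.call_status == frame_mod.UNRESOLVED for n in active)
        if live < inflated:
            active.extend(reserve.draw(inflated - live))

    # close-out: numbers still mid-resolution are written off and replaced a
    # final time so every generated number lands in a terminal state
    replacements += dialer_mod.sequential_replacement(active, reserve, 0)
    audit = dialer_mod.audit_conservation(frame.all_numbers, replacements)

    # --- respondents and weights ------------------------------------------
    resp = [(r.respondent_id, r.stratum) for r in records
            if r.outcome == dialer_mod.ANSWERED_COMPLETE]
    if not resp:
        raise RuntimeError("arm finished with zero completed interviews")
    ids = np.array([i for i, _ in resp])
    strata = [k for _, k in resp]
    ws = weights_mod.poststratification_weights(strata, ref, respondent_ids=ids)
    estimate_poststrat = weights_mod.weighted_estimate(pop.outcome[ids], ws).estimate

    nr_table = engine.nonresponse_table()
    full_table = {k: nr_table.get(k, 0.0) for k in set(strata)}
    ws_full = weights_mod.nonresponse_adjustment(ws, full_table)
    ws_full = weights_mod.multiphone_adjustment(ws_full, pop.n_phones[ids])
    final = weights_mod.weighted_estimate(pop.outcome[ids], ws_full)

    owner_truth = pop.mean_outcome(owners_only=True)
    full_truth = pop.mean_outcome()
    targets = plan.targets if plan is not None else {k: 0 for k in engine.states}

    return ArmResult(
        name="aasm" if quota_enabled else "rdd",
        completions=engine.completions, calls=engine.calls, stages=stage,
        numbers_generated=len(frame.all_numbers), replacements=replacements,
        targets=dict(targets), achieved=engine.achieved(),
        estimate_unweighted=float(pop.outcome[ids].mean()),
        estimate_poststrat=estimate_poststrat,
        estimate_final=final.estimate, se_final=final.se,
        cv_wt=ws_full.cv, deff_wt=ws_full.deff, effective_n=ws_full.effective_n,
        bias_owner=final.estimate - owner_truth,
        bias_full=final.estimate - full_truth,
        nonworking_fraction_used=y_used, audit=dict(audit),
        weight_set=ws_full, records=records,
        strata_table=engine.states_frame(pop.dimensions))


def run_scenario(config: ScenarioConfig, seed: Optional[int] = None,
                 log=None) -> ComparisonReport:
    """Both arms, shared population/frame seeds, one report."""
    master = config.seed if seed is None else seed
    _refuse_unfillable(config)
    pop = generate_population(config.population, substream(master, "population"))
    arm_aasm = run_arm(config, quota_enabled=True, seed=master, log=log)
    arm_rdd = run_arm(config, quota_enabled=False, seed=master, log=log)
    return ComparisonReport(
        config_name=config.name, seed=master,
        owner_truth=pop.mean_outcome(owners_only=True),
        full_truth=pop.mean_outcome(),
        aasm=arm_aasm, rdd=arm_rdd)


def _refuse_unfillable(config: ScenarioConfig) -> None:
    """A zero-ownership stratum with the stopping rules disabled can never
    terminate; refuse to start such a run."""
    stopping = config.aasm.stopping
    no_rule = (stopping.effort_factor == float("inf")
               and stopping.global_call_ceiling is None)
    if not no_rule:
        return
    for s in config.population.strata:
        if s.ownership == 0.0 and s.size > 0:
            raise ValueError(
                f"stratum {s.levels} has zero phone ownership and stopping "
                "rules are disabled; its quota can never be met")
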
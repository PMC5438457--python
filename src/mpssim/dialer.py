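"""Call-outcome simulation and accelerated sequential replacement.

Each dial of a number resolves against the synthetic population: nonworking
numbers ring out (or return an operator invalid-number signal, where the
network provides one), working numbers are answered with the owner's
propensity modulated by the time of day, and answered calls flow through
refusal, stratum screening, quota admission, possible mid-interview dropout
and completion.  Between operational stages — or immediately, in automated
mode — numbers verified nonworking (including numbers still unresolved after
the redial limit, which are written off as nonworking) are replaced by an
equal count of fresh unique numbers, keeping the active sample at size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aasm import ADMIT, QuotaEngine
from .config import DialerConfig, TIME_SLOTS
from .frame import (UNRESOLVED, VERIFIED_HOUSEHOLD, VERIFIED_NONWORKING,
                    PhoneNumber, Reserve)
from .population import Person, Population, StratumKey

# call outcomes
NONWORKING_SIGNAL = "nonworking_signal"
NO_ANSWER = "no_answer"
ANSWERED_REFUSED = "answered_refused"
ANSWERED_EXCUSED = "answered_excused"
ANSWERED_COMPLETE = "answered_complete"
ANSWERED_DROPOUT = "answered_dropout"

#: questionnaire modules whose order is randomized per completed interview,
#: so every module gets early placement across the sample (dropout hedge)
SURVEY_MODULES = ("demographics", "health_behaviour", "risk_factors")


@dataclass(frozen=True)
class CallRecord:
    number: str
    stage: int
    outcome: str
    time_slot: str
    respondent_id: Optional[int] = None
    stratum: Optional[StratumKey] = None
    referral: bool = False
    module_order: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if (self.respondent_id is not None) != self.outcome.startswith("answered"):
            raise ValueError("respondent_id present iff the call was answered")


def records_to_frame(records: Sequence[CallRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"stage": [r.stage for r in records],
         "number": [r.number for r in records],
         "outcome": [r.outcome for r in records],
         "time_slot": [r.time_slot for r in records],
         "respondent_id": [r.respondent_id for r in records],
         "stratum": ["|".join(r.stratum) if r.stratum else None for r in records],
         "referral": [r.referral for r in records]})


def randomize_time_slots(slot_weights: Dict[str, float], n: int,
                         rng: np.random.Generator) -> List[str]:
    """Draw i.i.d. call time slots from the configured weights."""
    slots = [s for s in TIME_SLOTS if slot_weights.get(s, 0.0) > 0]
    probs = np.array([slot_weights[s] for s in slots], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("slot weights must sum to 1")
    idx = rng.choice(len(slots), size=n, p=probs)
    return [slots[i] for i in idx]


def _answer_probability(person: Person, time_slot: str, config: DialerConfig) -> float:
    p = person.answer_propensity * config.slot_modifiers.get(time_slot, 1.0)
    # a non-primary (shared-handset) user only has the phone in the evening
    if not person.primary_user and time_slot != "evening":
        return 0.0
    return min(max(p, 0.0), 1.0)


def process_respondent(person: Person, number: PhoneNumber, stage: int,
                       time_slot: str, rng: np.random.Generator,
                       config: DialerConfig, engine: QuotaEngine,
                       population: Population, referral: bool = False) -> CallRecord:
    """Refusal -> screening -> quota decision -> dropout/completion for one
    answered respondent (direct or snowball-referred)."""
    common = dict(number=number.digits, stage=stage, time_slot=time_slot,
                  respondent_id=person.id, referral=referral)
    if rng.random() >= person.response_propensity:
        engine.record_refusal(person.stratum)
        return CallRecord(outcome=ANSWERED_REFUSED, stratum=person.stratum, **common)
    key = engine.screen(person)
    if engine.decide(key, person.id) != ADMIT:
        engine.record_excused()
        return CallRecord(outcome=ANSWERED_EXCUSED, stratum=key, **common)
    if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
        engine.record_dropout(key, person.id)
        return CallRecord(outcome=ANSWERED_DROPOUT, stratum=key, **common)
    engine.record_completion(key, person.id)
    order = tuple(SURVEY_MODULES[i] for i in rng.permutation(len(SURVEY_MODULES)))
    return CallRecord(outcome=ANSWERED_COMPLETE, stratum=key, module_order=order, **common)


def dial(number: PhoneNumber, population: Population, time_slot: str,
         rng: np.random.Generator, config: DialerConfig,
         engine: QuotaEngine, stage: int = 0) -> CallRecord:
    """One call attempt against one number."""
    if number.call_status != UNRESOLVED:
        raise RuntimeError(f"dialing a number already {number.call_status}")
    number.attempts += 1
    engine.calls += 1
    if not number.working:
        if config.operator_feedback:
            number.call_status = VERIFIED_NONWORKING
            return CallRecord(number=number.digits, stage=stage,
                              outcome=NONWORKING_SIGNAL, time_slot=time_slot)
        return CallRecord(number=number.digits, stage=stage,
                          outcome=NO_ANSWER, time_slot=time_slot)

    person = population.person(number.owner_id)
    if rng.random() >= _answer_probability(person, time_slot, config):
        return CallRecord(number=number.digits, stage=stage,
                          outcome=NO_ANSWER, time_slot=time_slot)
    # answered: the number is a verified household either way
    number.call_status = VERIFIED_HOUSEHOLD
    return process_respondent(person, number, stage, time_slot, rng, config,
                              engine, population)


def reclassify_unresolved(pool: Sequence[PhoneNumber], max_redials: int) -> int:
    """Write off numbers still unresolved after the redial limit as nonworking."""
    n = 0
    for num in pool:
        if num.call_status == UNRESOLVED and num.attempts >= max_redials + 1:
            num.call_status = VERIFIED_NONWORKING
            n += 1
    return n


def sequential_replacement(pool: List[PhoneNumber], reserve: Reserve,
                           max_redials: int) -> int:
    """Replace every not-yet-replaced verified-nonworking number (after
    reclassifying unresolved numbers past the redial limit) with an equal
    count of fresh unique numbers.  Returns how many were replaced."""
    reclassify_unresolved(pool, max_redials)
    to_replace = [n for n in pool if n.call_status == VERIFIED_NONWORKING and not n.replaced]
    fresh = reserve.draw(len(to_replace))
    for n in to_replace:
        n.replaced = True
    pool.extend(fresh)
    return len(to_replace)


def run_stage(pool: List[PhoneNumber], population: Population,
              config: DialerConfig, engine: QuotaEngine,
              rng: np.random.Generator, stage: int,
              reserve: Optional[Reserve] = None,
              call_ceiling: Optional[int] = None) -> Tuple[List[CallRecord], int]:
    """Dial every active (unresolved) number at most once, in random order.

    In automated mode (``config.automated_replacement`` with a reserve),
    numbers resolved nonworking are replaced immediately and their
    replacements join the same stage's queue.  Returns the stage's call
    records and the count of numbers replaced within the stage.
    """
    active = [n for n in pool if n.call_status == UNRESOLVED]
    order = rng.permutation(len(active))
    queue = [active[i] for i in order]
    records: List[CallRecord] = []
    automated = config.automated_replacement and reserve is not None
    replaced = 0
    i = 0
    while i < len(queue):
        if engine.done or (call_ceiling is not None and engine.calls >= call_ceiling):
            break
        number = queue[i]
        i += 1
        slot = randomize_time_slots(config.slot_weights, 1, rng)[0]
        rec = dial(number, population, slot, rng, config, engine, stage=stage)
        records.append(rec)
        if rec.outcome in (ANSWERED_EXCUSED, ANSWERED_COMPLETE):
            member = engine.try_snowball(rec.respondent_id, population, rng)
            if member is not None:
                records.append(process_respondent(
                    member, number, stage, slot, rng, config, engine,
                    population, referral=True))
        if automated:
            if number.call_status == UNRESOLVED and number.attempts >= config.max_redials + 1:
                number.call_status = VERIFIED_NONWORKING
            if number.call_status == VERIFIED_NONWORKING and not number.replaced:
                fresh = reserve.draw(1)
                number.replaced = True
                pool.extend(fresh)
                queue.extend(fresh)
                replaced += 1
    return records, replaced


def audit_conservation(all_numbers: Sequence[PhoneNumber], replacements: int) -> Dict[str, int]:
    """End-of-run audit: every generated number must sit in exactly one
    terminal state, and replacements must equal verified-nonworking numbers."""
    tally = {VERIFIED_HOUSEHOLD: 0, VERIFIED_NONWORKING: 0, "surplus": 0}
    for num in all_numbers:
        if num.call_status == VERIFIED_HOUSEHOLD:
            tally[VERIFIED_HOUSEHOLD] += 1
        elif num.call_status == VERIFIED_NONWORKING:
            tally[VERIFIED_NONWORKING] += 1
        elif num.call_status == UNRESOLVED and num.attempts == 0:
            tally["surplus"] += 1
        else:
            raise AssertionError(
                f"number {num.digits} left {num.call_status} after {num.attempts} attempts")
    if sum(tally.values()) != len(all_numbers):
        raise AssertionError("terminal states do not partition the generated numbers")
    if replacements != tally[VERIFIED_NONWORKING]:
        raise AssertionError(
            f"{replacements} replacements vs {tally[VERIFIED_NONWORKING]} verified nonworking")
    tally["replacements"] = replacements
    return tally
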
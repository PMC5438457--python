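"""Automated active strata monitoring (AASM): the real-time quota engine.

Every answering, non-refusing respondent is screened for their demographic
stratum.  If the stratum is still open they are led through the interview;
once a stratum's quota of completed interviews is reached it is closed and
later arrivals from it are excused without further questions.  Sampling is
without replacement — nobody is interviewed twice, even when a second of
their phones is reached.  Stopping rules abandon strata that soak up effort
without filling (e.g. groups with near-zero phone ownership), and an
optional snowball mechanism asks a respondent to hand the phone to a
household member from a still-needed stratum.

Quotas are set from a census-style reference distribution, so at clean
termination the sample's strata composition equals the population's — which
is what drives the engine's headline effect: poststratification weights
near 1 and a design effect near the simple-random-sampling ideal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

from ._util import largest_remainder
from .config import SnowballConfig, StoppingConfig
from .population import Person, Population, ReferenceDistribution, StratumKey

OPEN = "open"
CLOSED = "closed"
ABANDONED = "abandoned"

ADMIT = "admit"
EXCUSE = "excuse"


@dataclass
class StratumState:
    """Live bookkeeping for one quota cell."""

    key: StratumKey
    target: int
    filled: int = 0
    status: str = OPEN
    #: screened respondents mapped to this stratum (a measure of effort spent)
    effort: int = 0

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ValueError("target must be non-negative")


@dataclass(frozen=True)
class QuotaPlan:
    targets: Dict[StratumKey, int]
    total_n: int

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.targets.values()):
            raise ValueError("targets must be non-negative")
        if sum(self.targets.values()) != self.total_n:
            raise ValueError("targets must sum to total_n")


def make_quota_plan(reference: ReferenceDistribution, total_n: int) -> QuotaPlan:
    """Per-stratum targets proportional to the reference, summing exactly to
    ``total_n`` (largest-remainder rounding)."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    keys = list(reference.keys())
    if not keys:
        raise ValueError("empty reference distribution")
    alloc = largest_remainder([reference[k] for k in keys], total_n)
    return QuotaPlan({k: int(a) for k, a in zip(keys, alloc)}, total_n)


def admit_or_excuse(state: StratumState) -> str:
    """Quota decision for a screened respondent: admit iff the stratum is open."""
    return ADMIT if state.status == OPEN else EXCUSE


def stopping_rule(states: Dict[StratumKey, StratumState], stopping: StoppingConfig,
                  global_calls: int, ceiling: int) -> List[StratumKey]:
    """Strata to abandon: open cells past their effort ceiling, or every open
    cell once the global call ceiling is hit."""
    out: List[StratumKey] = []
    for key, st in states.items():
        if st.status != OPEN:
            continue
        if global_calls >= ceiling:
            out.append(key)
        elif st.effort >= stopping.effort_factor * max(st.target, 1):
            out.append(key)
    return out


class QuotaEngine:
    """Interview admission controller for one survey arm.

    With a :class:`QuotaPlan` it enforces AASM; with ``plan=None`` it is the
    unrestricted-RDD comparator — identical pipeline, but every screened
    respondent is admitted until ``total_n`` interviews are complete (strata
    are still tracked for reporting, never closed).
    """

    def __init__(self, plan: Optional[QuotaPlan], total_n: int,
                 stopping: Optional[StoppingConfig] = None,
                 snowball: Optional[SnowballConfig] = None,
                 log=None) -> None:
        self.plan = plan
        self.total_n = int(total_n)
        self.stopping = stopping or StoppingConfig()
        self.snowball = snowball or SnowballConfig()
        self.log = log  # callable(str) for the live progress stream
        self.states: Dict[StratumKey, StratumState] = {}
        if plan is not None:
            for key, target in plan.targets.items():
                self.states[key] = StratumState(key=key, target=target)
                if target == 0:
                    self.states[key].status = CLOSED
        self.calls = 0
        self.completions = 0
        self.interviewed: Set[int] = set()
        self.refusals: Dict[StratumKey, int] = {}
        self.dropouts: Dict[StratumKey, int] = {}
        self.excused = 0

    # -- helpers -----------------------------------------------------------
    @property
    def quota_enabled(self) -> bool:
        return self.plan is not None

    def _emit(self, msg: str) -> None:
        if self.log is not None:
            self.log(msg)

    def _state(self, key: StratumKey) -> StratumState:
        if key not in self.states:
            if self.quota_enabled:
                raise KeyError(f"respondent stratum {key} outside the declared quota cells")
            self.states[key] = StratumState(key=key, target=0)
        return self.states[key]

    @property
    def done(self) -> bool:
        if self.quota_enabled:
            return all(st.status != OPEN for st in self.states.values())
        return self.completions >= self.total_n

    # -- the AASM operations ----------------------------------------------
    def screen(self, person: Person) -> StratumKey:
        """First questions: establish the stratum; counts toward effort."""
        key = person.stratum
        self._state(key).effort += 1
        return key

    def decide(self, key: StratumKey, person_id: int) -> str:
        """Admit or excuse a screened respondent (without replacement)."""
        if person_id in self.interviewed:
            return EXCUSE
        if self.quota_enabled:
            return admit_or_excuse(self.states[key])
        return ADMIT if self.completions < self.total_n else EXCUSE

    def record_completion(self, key: StratumKey, person_id: int) -> None:
        st = self._state(key)
        if self.quota_enabled and st.status != OPEN:
            raise RuntimeError(f"completion recorded into non-open stratum {key}")
        st.filled += 1
        self.completions += 1
        self.interviewed.add(person_id)
        if self.quota_enabled and st.filled >= st.target:
            st.status = CLOSED
            self._emit(f"stratum {key} closed at {st.filled}/{st.target}")

    def record_dropout(self, key: StratumKey, person_id: int) -> None:
        # dropouts do not fill quota, but the person is not re-interviewed
        self.dropouts[key] = self.dropouts.get(key, 0) + 1
        self.interviewed.add(person_id)

    def record_refusal(self, key: StratumKey) -> None:
        self.refusals[key] = self.refusals.get(key, 0) + 1

    def record_excused(self) -> None:
        self.excused += 1

    def apply_stopping(self, ceiling: int) -> List[StratumKey]:
        if not self.quota_enabled:
            return []
        to_abandon = stopping_rule(self.states, self.stopping, self.calls, ceiling)
        for key in to_abandon:
            self.states[key].status = ABANDONED
            self._emit(f"stratum {key} abandoned at {self.states[key].filled}"
                       f"/{self.states[key].target} after effort {self.states[key].effort}")
        return to_abandon

    def try_snowball(self, respondent_id: int, population: Population,
                     rng: np.random.Generator) -> Optional[Person]:
        """Ask the respondent to hand the phone to a household member from a
        still-open stratum; returns that member on success."""
        if not self.snowball.enabled or not self.quota_enabled:
            return None
        person = population.person(respondent_id)
        members = population.household_members(person.household)
        needed = []
        for mid in members:
            mid = int(mid)
            if mid == respondent_id or mid in self.interviewed:
                continue
            key = population.stratum_of(mid)
            st = self.states.get(key)
            if st is not None and st.status == OPEN and st.filled < st.target:
                needed.append(mid)
        if not needed:
            return None
        if rng.random() >= self.snowball.success_prob:
            return None
        return population.person(int(needed[int(rng.integers(len(needed)))]))

    # -- reporting ---------------------------------------------------------
    def achieved(self) -> Dict[StratumKey, int]:
        return {k: st.filled for k, st in self.states.items()}

    def nonresponse_table(self) -> Dict[StratumKey, float]:
        """Per-stratum nonresponse rate f = nonrespondents / eligible contacts.

        Nonrespondents are refusals plus mid-interview dropouts; excused
        respondents are not eligible (their stratum was full) and do not
        count.
        """
        table: Dict[StratumKey, float] = {}
        keys = set(self.states) | set(self.refusals) | set(self.dropouts)
        for key in keys:
            comp = self.states[key].filled if key in self.states else 0
            nonresp = self.refusals.get(key, 0) + self.dropouts.get(key, 0)
            denom = comp + nonresp
            if denom > 0:
                table[key] = nonresp / denom
        return table

    def states_frame(self, dimensions) -> pd.DataFrame:
        rows = [dict(zip(dimensions, k),
                     target=st.target, filled=st.filled,
                     status=st.status, effort=st.effort)
                for k, st in self.states.items()]
        return pd.DataFrame(rows)


def snowball_referral(engine: QuotaEngine, respondent: Person,
                      population: Population, rng: np.random.Generator) -> Optional[Person]:
    """Module-level convenience over :meth:`QuotaEngine.try_snowball`."""
    return engine.try_snowball(respondent.id, population, rng)
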
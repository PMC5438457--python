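"""RDD sampling-frame construction.

Candidate numbers are generated inside each operator's prefix block,
proportionally to market share (largest-remainder apportionment, so the
pool's prefix composition is exact), unique across every batch ever drawn in
a run.  A configurable fraction Y of each batch is nonworking; working
numbers are linked uniformly at random to the population's phone slots (a
person owning T phones holds T slots), which is what makes selection
probability proportional to the number of phones owned.

The batch composition is exact — round(m*(1-Y)) working numbers out of m —
while which numbers are working, and whose phone each rings, is random.
Inflating a target sample size by 1/(1-Y) therefore buys exactly the working
contacts it promises, and the pilot "test pool" estimate of Y carries
ordinary binomial error.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import largest_remainder
from .config import MnoPlanConfig
from .population import Population

# call statuses (shared with the dialer)
UNRESOLVED = "unresolved"
VERIFIED_HOUSEHOLD = "verified_household"
VERIFIED_NONWORKING = "verified_nonworking"
_RESOLVED = (VERIFIED_HOUSEHOLD, VERIFIED_NONWORKING)


class FrameExhaustedError(RuntimeError):
    """The operator number space cannot supply more unique numbers."""


@dataclass(eq=False)
class PhoneNumber:
    """A dialable number with its replacement-engine bookkeeping."""

    digits: str
    prefix: str
    working: bool = False
    owner_id: Optional[int] = None
    call_status: str = UNRESOLVED
    attempts: int = 0
    batch: int = 0
    replaced: bool = field(default=False, repr=False)


@dataclass
class NumberPool:
    numbers: List[PhoneNumber]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.numbers)

    def __iter__(self):
        return iter(self.numbers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"number": [n.digits for n in self.numbers],
             "prefix": [n.prefix for n in self.numbers],
             "batch": [n.batch for n in self.numbers],
             "status": [n.call_status for n in self.numbers],
             "attempts": [n.attempts for n in self.numbers]})


@dataclass(frozen=True)
class MnoPlan:
    prefix: str
    suffix_length: int
    market_share: float

    @property
    def space(self) -> int:
        return 10 ** self.suffix_length

    @classmethod
    def from_config(cls, cfg: MnoPlanConfig) -> "MnoPlan":
        return cls(cfg.prefix, cfg.suffix_length, cfg.market_share)


@dataclass(frozen=True)
class FramePlan:
    """Sample-size plan: target completions inflated for nonworking numbers."""

    target_n: int
    nonworking_fraction: float
    inflated_n: int


def _as_plans(plans: Sequence) -> List[MnoPlan]:
    out = [p if isinstance(p, MnoPlan) else MnoPlan.from_config(p) for p in plans]
    prefixes = [p.prefix for p in out]
    if len(set(prefixes)) != len(prefixes):
        raise ValueError("duplicate MNO prefixes")
    if abs(sum(p.market_share for p in out) - 1.0) > 1e-9:
        raise ValueError("market shares must sum to 1")
    return out


class NumberFrame:
    """Generates unique candidate numbers and links them to the population.

    One frame instance owns the run-wide uniqueness guarantee ("care taken
    not to re-create numbers"): every batch is disjoint from every earlier
    batch.  When a population is attached, each batch gets exactly
    round(size*(1-Y)) working numbers (fewer if phone slots run out), each
    ringing a distinct randomly-chosen phone slot.
    """

    def __init__(self, plans: Sequence, rng: np.random.Generator,
                 population: Optional[Population] = None,
                 nonworking_fraction: float = 0.0) -> None:
        if not (0.0 <= nonworking_fraction < 1.0):
            raise ValueError("nonworking fraction must be in [0, 1)")
        self.plans = _as_plans(plans)
        self.rng = rng
        self.population = population
        self.nonworking_fraction = float(nonworking_fraction)
        self._used: set[str] = set()
        self._used_per_prefix = {p.prefix: 0 for p in self.plans}
        self._batches = 0
        self.all_numbers: List[PhoneNumber] = []
        if population is not None:
            slots = np.repeat(np.arange(population.size), population.n_phones)
            self._slots = deque(int(i) for i in rng.permutation(slots))
        else:
            self._slots = deque()

    @property
    def batches_generated(self) -> int:
        return self._batches

    def _draw_suffixes(self, plan: MnoPlan, k: int) -> List[str]:
        if self._used_per_prefix[plan.prefix] + k > plan.space:
            raise FrameExhaustedError(
                f"prefix {plan.prefix}: requested {k} more numbers, "
                f"only {plan.space - self._used_per_prefix[plan.prefix]} left")
        out: List[str] = []
        width = plan.suffix_length
        while len(out) < k:
            cand = self.rng.integers(0, plan.space, size=max(2 * (k - len(out)), 16))
            for c in cand:
                digits = plan.prefix + str(int(c)).zfill(width)
                if digits not in self._used:
                    self._used.add(digits)
                    out.append(digits)
                    if len(out) == k:
                        break
        self._used_per_prefix[plan.prefix] += k
        return out

    def new_batch(self, size: int) -> NumberPool:
        """A fresh batch of ``size`` unique numbers, prefix-proportional."""
        if size < 0:
            raise ValueError("batch size must be non-negative")
        gen = self._batches
        self._batches += 1
        if size == 0:
            return NumberPool([], generation=gen)
        alloc = largest_remainder([p.market_share for p in self.plans], size)
        numbers: List[PhoneNumber] = []
        for plan, k in zip(self.plans, alloc):
            for digits in self._draw_suffixes(plan, int(k)):
                numbers.append(PhoneNumber(digits=digits, prefix=plan.prefix, batch=gen))
        # shuffle so dialing order is not blocked by operator
        order = self.rng.permutation(len(numbers))
        numbers = [numbers[i] for i in order]

        if self.population is not None:
            n_working = min(int(round(size * (1.0 - self.nonworking_fraction))),
                            len(self._slots))
            which = self.rng.choice(size, size=n_working, replace=False)
            for i in which:
                num = numbers[int(i)]
                num.working = True
                num.owner_id = self._slots.popleft()
        self.all_numbers.extend(numbers)
        return NumberPool(numbers, generation=gen)


def build_number_pool(plans: Sequence, pool_size: int, seed,
                      population: Optional[Population] = None,
                      nonworking_fraction: float = 0.0) -> NumberPool:
    """One-shot pool construction (convenience over :class:`NumberFrame`)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = NumberFrame(plans, rng, population=population,
                        nonworking_fraction=nonworking_fraction)
    return frame.new_batch(pool_size)


class Reserve:
    """Pre-generated surplus numbers, replenished from the frame on demand."""

    def __init__(self, frame: NumberFrame, initial: Optional[NumberPool] = None,
                 batch_size: int = 1000) -> None:
        self.frame = frame
        self.batch_size = max(int(batch_size), 1)
        self._queue: deque[PhoneNumber] = deque(initial.numbers if initial else [])

    def __len__(self) -> int:
        return len(self._queue)

    def draw(self, k: int) -> List[PhoneNumber]:
        while len(self._queue) < k:
            self._queue.extend(self.frame.new_batch(self.batch_size).numbers)
        return [self._queue.popleft() for _ in range(k)]

    @property
    def remaining(self) -> List[PhoneNumber]:
        return list(self._queue)


def estimate_nonworking_fraction(test_pool_outcomes: Iterable[str]) -> Tuple[float, float]:
    """Estimate Y from a practice round: share of resolved numbers that were
    nonworking, with its binomial standard error."""
    outcomes = list(test_pool_outcomes)
    resolved = [o for o in outcomes if o in _RESOLVED]
    if not resolved:
        raise ValueError("no resolved outcomes in test pool")
    m = len(resolved)
    y = sum(o == VERIFIED_NONWORKING for o in resolved) / m
    se = math.sqrt(y * (1.0 - y) / m)
    return y, se


def inflate_sample_size(target_n: int, nonworking_fraction: float) -> int:
    """Numbers to generate so that ~target_n of them are working: n/(1-Y)."""
    if target_n < 0:
        raise ValueError("target_n must be non-negative")
    if not (0.0 <= nonworking_fraction < 1.0):
        raise ValueError("nonworking fraction must be in [0, 1); Y >= 1 means "
                         "no working numbers exist")
    value = target_n / (1.0 - nonworking_fraction)
    # guard the ceiling against float noise (e.g. 1000/(1-0.9) = 10000.000...2)
    return math.ceil(value * (1.0 - 1e-12))


def frame_plan(target_n: int, nonworking_fraction: float) -> FramePlan:
    return FramePlan(target_n, nonworking_fraction,
                     inflate_sample_size(target_n, nonworking_fraction))
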
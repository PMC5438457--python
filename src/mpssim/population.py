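"""Synthetic stratified populations with inequitable mobile-phone ownership.

A population is a cross-section of persons, each belonging to exactly one
demographic stratum (a cell of the Cartesian product of declared dimensions,
e.g. sex x age band x urban/rural).  Phone ownership is configurable per
stratum, so the simulator can realize anything from low-penetration settings
(whole strata nearly unreachable by phone) to near-universal saturation.
Each person carries:

* ``n_phones`` — how many mobile phones they own (0 means unreachable by a
  phone survey; more than 1 raises their selection probability under random
  digit dialing proportionally),
* answer/response propensities — probability of picking up a call, and of
  completing the interview given that they answered,
* a binary health outcome whose population prevalence is the estimand.

Per-stratum sizes are allocated exactly (deterministic), while ownership,
phone counts and outcomes are stochastic draws, so the census-style reference
distribution is exact by construction and the sampling noise lives where a
survey actually meets it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PopulationConfig

#: A stratum is identified by its tuple of categorical levels, ordered as the
#: scenario's dimension names.
StratumKey = Tuple[str, ...]


@dataclass(frozen=True)
class Person:
    """A single synthetic individual (a read-only view into a Population)."""

    id: int
    stratum: StratumKey
    n_phones: int
    answer_propensity: float
    response_propensity: float
    outcome: float
    household: int
    primary_user: bool

    @property
    def reachable(self) -> bool:
        return self.n_phones >= 1


@dataclass(frozen=True)
class ReferenceDistribution:
    """Census-style strata proportions: StratumKey -> population share.

    This is the quota engine's and the poststratification step's external
    benchmark (in a real survey: recent census or DHS margins).
    """

    dimensions: Tuple[str, ...]
    proportions: Mapping[StratumKey, float]

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError("reference distribution is empty")
        vals = np.array(list(self.proportions.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("proportions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {vals.sum()!r}, not 1")
        for key in self.proportions:
            if len(key) != len(self.dimensions):
                raise ValueError(f"key {key} does not match dimensions {self.dimensions}")

    def __getitem__(self, key: StratumKey) -> float:
        return self.proportions[key]

    def __contains__(self, key: StratumKey) -> bool:
        return key in self.proportions

    def keys(self):
        return self.proportions.keys()

    def items(self):
        return self.proportions.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(zip(self.dimensions, k), proportion=p) for k, p in self.proportions.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dimensions: Iterable[str]) -> "ReferenceDistribution":
        dims = tuple(dimensions)
        df = pd.read_csv(path, dtype={d: str for d in dims})
        props = {tuple(row[d] for d in dims): float(row["proportion"]) for _, row in df.iterrows()}
        return cls(dims, props)

    @classmethod
    def from_counts(cls, dimensions: Iterable[str], counts: Mapping[StratumKey, int]) -> "ReferenceDistribution":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("counts sum to zero")
        return cls(tuple(dimensions), {k: c / total for k, c in counts.items()})


@dataclass
class Population:
    """A generated cross-section, stored columnwise for vectorized access."""

    dimensions: Tuple[str, ...]
    strata_keys: Tuple[StratumKey, ...]
    stratum_index: np.ndarray  # int, per person
    n_phones: np.ndarray  # int, per person
    answer_propensity: np.ndarray
    response_propensity: np.ndarray
    outcome: np.ndarray
    household: np.ndarray
    primary_user: np.ndarray
    _households: Optional[Dict[int, np.ndarray]] = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return int(self.stratum_index.size)

    @property
    def owner_mask(self) -> np.ndarray:
        return self.n_phones >= 1

    @property
    def total_phones(self) -> int:
        return int(self.n_phones.sum())

    def stratum_of(self, person_id: int) -> StratumKey:
        return self.strata_keys[int(self.stratum_index[person_id])]

    def person(self, person_id: int) -> Person:
        i = int(person_id)
        return Person(
            id=i,
            stratum=self.strata_keys[int(self.stratum_index[i])],
            n_phones=int(self.n_phones[i]),
            answer_propensity=float(self.answer_propensity[i]),
            response_propensity=float(self.response_propensity[i]),
            outcome=float(self.outcome[i]),
            household=int(self.household[i]),
            primary_user=bool(self.primary_user[i]),
        )

    def counts(self, owners_only: bool = False) -> Dict[StratumKey, int]:
        mask = self.owner_mask if owners_only else np.ones(self.size, dtype=bool)
        binc = np.bincount(self.stratum_index[mask], minlength=len(self.strata_keys))
        return {k: int(binc[i]) for i, k in enumerate(self.strata_keys)}

    def household_members(self, household_id: int) -> np.ndarray:
        if self._households is None:
            order = np.argsort(self.household, kind="stable")
            hh = self.household[order]
            splits = np.flatnonzero(np.diff(hh)) + 1
            groups = np.split(order, splits)
            self._households = {int(self.household[g[0]]): g for g in groups}
        return self._households[int(household_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "person_id": np.arange(self.size),
            "n_phones": self.n_phones,
            "answer_propensity": self.answer_propensity,
            "response_propensity": self.response_propensity,
            "outcome": self.outcome,
            "household": self.household,
            "primary_user": self.primary_user,
        })
        for j, dim in enumerate(self.dimensions):
            df[dim] = [self.strata_keys[i][j] for i in self.stratum_index]
        return df

    # --- estimand ground truths -------------------------------------------
    def mean_outcome(self, owners_only: bool = False) -> float:
        mask = self.owner_mask if owners_only else slice(None)
        return float(self.outcome[mask].mean())


def generate_population(config: PopulationConfig, seed) -> Population:
    """Synthesize a population from a scenario's declared strata.

    Deterministic given (config, seed): per-stratum sizes are exact, phone
    ownership and counts are drawn from the stratum's ownership model, the
    binary outcome from the stratum prevalence.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    dims = tuple(config.dimensions)
    keys: list[StratumKey] = []
    stratum_index = []
    n_phones = []
    answer = []
    response = []
    outcome = []
    primary = []

    for idx, spec in enumerate(config.strata):
        key = tuple(spec.levels)
        keys.append(key)
        n = spec.size
        stratum_index.append(np.full(n, idx, dtype=np.int64))

        owner = rng.random(n) < spec.ownership
        dist = spec.phone_counts if spec.phone_counts is not None else config.phone_counts
        values = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([dist[int(v)] for v in values], dtype=float)
        counts = rng.choice(values, size=n, p=probs)
        n_phones.append(np.where(owner, counts, 0))

        answer.append(np.full(n, spec.answer_propensity))
        response.append(np.full(n, spec.response_propensity))
        outcome.append((rng.random(n) < spec.prevalence).astype(float))
        # shared-phone holders are non-primary users: they only pick up in the
        # evening, when the handset is back in the household
        primary.append(~(owner & (rng.random(n) < spec.shared_phone_rate)))

    stratum_index = np.concatenate(stratum_index)
    total = stratum_index.size

    # households are assigned across strata so that snowball referral can
    # reach a member of a different (possibly hard-to-fill) stratum
    sizes_dist = config.household_size
    hvalues = np.array(sorted(sizes_dist), dtype=np.int64)
    hprobs = np.array([sizes_dist[int(v)] for v in hvalues], dtype=float)
    household = np.empty(total, dtype=np.int64)
    perm = rng.permutation(total)
    pos = 0
    hid = 0
    while pos < total:
        k = int(rng.choice(hvalues, p=hprobs))
        household[perm[pos:pos + k]] = hid
        pos += k
        hid += 1

    return Population(
        dimensions=dims,
        strata_keys=tuple(keys),
        stratum_index=stratum_index,
        n_phones=np.concatenate(n_phones),
        answer_propensity=np.concatenate(answer),
        response_propensity=np.concatenate(response),
        outcome=np.concatenate(outcome),
        household=household,
        primary_user=np.concatenate(primary),
    )


def reference_distribution(population: Population, owners_only: bool = False) -> ReferenceDistribution:
    """Exact strata proportions of the population (the census benchmark).

    With ``owners_only=True`` the distribution is over phone owners — the
    reachable frame — which is the right calibration target when estimating
    means of the phone-owning population (census/DHS phone-ownership margins
    play this role in the field).
    """
    counts = population.counts(owners_only=owners_only)
    counts = {k: c for k, c in counts.items() if c > 0} if owners_only else counts
    if population.size == 0 or sum(counts.values()) == 0:
        raise ValueError("empty population")
    return ReferenceDistribution.from_counts(population.dimensions, counts)


def ownership_gap_report(population: Population) -> pd.DataFrame:
    """Per-stratum ownership rates and owner-vs-nonowner outcome gaps.

    Quantifies the presampling coverage bias: strata with low ownership are
    under-covered by any phone frame, and if owners differ from non-owners on
    the outcome, no amount of within-frame weighting can repair it.
    """
    rows = []
    for idx, key in enumerate(population.strata_keys):
        mask = population.stratum_index == idx
        n = int(mask.sum())
        owners = mask & population.owner_mask
        nonowners = mask & ~population.owner_mask
        n_own = int(owners.sum())
        rate = n_own / n if n else float("nan")
        mean_own = float(population.outcome[owners].mean()) if n_own else float("nan")
        mean_non = float(population.outcome[nonowners].mean()) if n - n_own else float("nan")
        if n_own == 0:
            flag = "unreachable"
        elif n_own == n:
            flag = "no non-owners"
        else:
            flag = ""
        rows.append(dict(zip(population.dimensions, key),
                         size=n, ownership_rate=rate,
                         mean_outcome_owners=mean_own,
                         mean_outcome_nonowners=mean_non,
                         gap=mean_own - mean_non if flag == "" else float("nan"),
                         flag=flag))
    return pd.DataFrame(rows)
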
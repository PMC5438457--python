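"""Scenario configuration schema (validated, fully serializable).

A :class:`ScenarioConfig` pins down everything a run needs — population
strata, ownership model, operator prefixes and shares, nonworking fraction,
dialer behaviour, quota-engine settings and the master seed — so two runs
from the same config are identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

TIME_SLOTS = ("morning", "afternoon", "evening")


def _check_dist(dist: Dict[int, float], what: str) -> Dict[int, float]:
    if not dist:
        raise ValueError(f"{what} distribution is empty")
    if any(k < 1 for k in dist):
        raise ValueError(f"{what} categories must be >= 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{what} probabilities must be non-negative")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1")
    return dist


class StratumConfig(BaseModel):
    """One demographic cell: exact size plus its ownership/outcome model."""

    levels: Tuple[str, ...]
    size: int = Field(ge=0)
    ownership: float = Field(ge=0.0, le=1.0)
    prevalence: float = Field(ge=0.0, le=1.0)
    answer_propensity: float = Field(default=0.7, ge=0.0, le=1.0)
    response_propensity: float = Field(default=0.85, ge=0.0, le=1.0)
    phone_counts: Optional[Dict[int, float]] = None
    shared_phone_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("phone_counts")
    @classmethod
    def _phone_counts_ok(cls, v):
        return None if v is None else _check_dist(v, "phone-count")


class PopulationConfig(BaseModel):
    dimensions: Tuple[str, ...]
    strata: List[StratumConfig]
    #: phone-count distribution among owners; the default reflects mostly
    #: single-handset ownership with a multi-SIM minority
    phone_counts: Dict[int, float] = Field(default_factory=lambda: {1: 0.85, 2: 0.10, 3: 0.05})
    household_size: Dict[int, float] = Field(default_factory=lambda: {1: 1.0})

    @field_validator("dimensions")
    @classmethod
    def _dims_ok(cls, v):
        if len(v) == 0:
            raise ValueError("at least one stratification dimension required")
        return v

    @field_validator("phone_counts")
    @classmethod
    def _counts_ok(cls, v):
        return _check_dist(v, "phone-count")

    @field_validator("household_size")
    @classmethod
    def _hh_ok(cls, v):
        return _check_dist(v, "household-size")

    @model_validator(mode="after")
    def _strata_ok(self):
        if not self.strata:
            raise ValueError("no strata declared")
        seen = set()
        for s in self.strata:
            if len(s.levels) != len(self.dimensions):
                raise ValueError(f"stratum {s.levels} does not match dimensions {self.dimensions}")
            if s.levels in seen:
                raise ValueError(f"duplicate stratum {s.levels}")
            seen.add(s.levels)
        return self


class MnoPlanConfig(BaseModel):
    """A mobile network operator's prefix, number-space size and market share."""

    prefix: str
    suffix_length: int = Field(default=7, ge=1)
    market_share: float = Field(ge=0.0, le=1.0)

    @field_validator("prefix")
    @classmethod
    def _prefix_digits(cls, v):
        if not v.isdigit():
            raise ValueError("prefix must be a digit string")
        return v


class FrameConfig(BaseModel):
    plans: List[MnoPlanConfig]
    #: true fraction of the number space that is nonworking (the frame's Y)
    nonworking_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    #: when true, Y is estimated from a practice round on a small test pool
    #: instead of being taken from config
    estimate_y: bool = False
    test_pool_size: int = Field(default=200, ge=1)
    #: reserve pool is this many times the inflated sample size
    pool_factor: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _plans_ok(self):
        if not self.plans:
            raise ValueError("at least one MNO plan required")
        prefixes = [p.prefix for p in self.plans]
        if len(set(prefixes)) != len(prefixes):
            raise ValueError("duplicate MNO prefixes")
        if abs(sum(p.market_share for p in self.plans) - 1.0) > 1e-9:
            raise ValueError("market shares must sum to 1")
        return self


class DialerConfig(BaseModel):
    #: redials allowed after the first unanswered call before the number is
    #: written off as nonworking
    max_redials: int = Field(default=3, ge=0)
    #: whether the operator signals invalid numbers on first dial
    operator_feedback: bool = True
    slot_weights: Dict[str, float] = Field(
        default_factory=lambda: {"morning": 1 / 3, "afternoon": 1 / 3, "evening": 1 / 3})
    #: per-slot multiplier on answer propensity (evening targeting etc.)
    slot_modifiers: Dict[str, float] = Field(
        default_factory=lambda: {"morning": 1.0, "afternoon": 1.0, "evening": 1.0})
    #: probability an admitted respondent drops out mid-interview
    dropout_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    #: replace invalid numbers immediately (automated) or at stage end (staged)
    automated_replacement: bool = False

    @field_validator("slot_weights", "slot_modifiers")
    @classmethod
    def _slots_ok(cls, v):
        if set(v) - set(TIME_SLOTS):
            raise ValueError(f"unknown time slots {set(v) - set(TIME_SLOTS)}")
        return v

    @model_validator(mode="after")
    def _weights_sum(self):
        if abs(sum(self.slot_weights.values()) - 1.0) > 1e-9:
            raise ValueError("slot weights must sum to 1")
        return self


class StoppingConfig(BaseModel):
    """When to abandon unfillable strata (the survey's stopping rules)."""

    #: abandon an open stratum once screened arrivals exceed this multiple of
    #: its target without filling it
    effort_factor: float = Field(default=50.0, gt=0.0)
    #: total-dial ceiling; None means 100 x total_n, chosen at run time
    global_call_ceiling: Optional[int] = Field(default=None, ge=1)


class SnowballConfig(BaseModel):
    enabled: bool = False
    success_prob: float = Field(default=0.5, ge=0.0, le=1.0)


class AasmConfig(BaseModel):
    stopping: StoppingConfig = Field(default_factory=StoppingConfig)
    snowball: SnowballConfig = Field(default_factory=SnowballConfig)


class ScenarioConfig(BaseModel):
    """Full experiment specification; the unit of reproducibility."""

    name: str = "scenario"
    total_n: int = Field(ge=1)
    population: PopulationConfig
    frame: FrameConfig
    dialer: DialerConfig = Field(default_factory=DialerConfig)
    aasm: AasmConfig = Field(default_factory=AasmConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScenarioConfig.model_validate(data)
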
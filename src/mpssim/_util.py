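"""Small shared numerics: integer apportionment and significant-figure rounding."""

from __future__ import annotations

import math
import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def largest_remainder(shares, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``shares``.

    Hamilton / largest-remainder rounding: every unit is assigned, floor
    allocations are topped up in decreasing order of fractional remainder
    (ties broken by position, so the rule is deterministic).
    """
    shares = np.asarray(shares, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if shares.size == 0:
        raise ValueError("no shares to apportion over")
    if np.any(shares < 0):
        raise ValueError("shares must be non-negative")
    s = shares.sum()
    if s <= 0:
        raise ValueError("shares sum to zero")
    raw = shares / s * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, half away from zero (0 stays 0).

    Works on the shortest decimal representation of ``x`` so that values like
    1.875e-8 round up to 1.88e-8 as they would on paper, rather than falling
    to the nearest binary float.
    """
    if x == 0 or not math.isfinite(x):
        return x
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(-shift)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG stream derived from one master seed.

    Each module of the pipeline draws from its own stream so toggling one
    stage (e.g. quota monitoring on/off) does not perturb another stage's
    draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))
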
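"""Postsampling weighting and design-effect diagnostics.

The survey weight of respondent *i* composes multiplicatively from

* a base weight (1 under equal-probability RDD),
* a poststratification factor  w_h = P_h / p_h  (population share over
  sample share of the respondent's stratum h), which calibrates the weighted
  strata composition to a census-style reference,
* a nonresponse factor  R_i = 1 / (1 - f_i), the inverse response rate of
  the respondent's group,
* a multiple-phone factor  A_i = 1 / T_i, undoing the T-fold selection
  advantage of a T-phone owner under random digit dialing.

Weight variability is what weighting costs: by Kish's approximation the
variance of a weighted estimate is inflated by

    deff_wt = 1 + CV_wt**2  =  n * sum(w_i**2) / (sum(w_i))**2,

where CV_wt is the coefficient of variation of the weights (population,
i.e. divide-by-n, standard deviation over the mean — the convention that
makes the two forms algebraically identical).  The effective sample size is
n / deff_wt.

Selection probabilities themselves are closed-form: a person owning N_p of
the N_T phones in the population has inclusion probability n * N_p / N_T
for a targeted sample of n.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .population import ReferenceDistribution, StratumKey


@dataclass(frozen=True)
class WeightSet:
    """Per-respondent weights with their multiplicative components."""

    strata: Tuple[StratumKey, ...]
    base: np.ndarray
    poststrat: np.ndarray
    nonresponse: np.ndarray
    multiphone: np.ndarray
    trim: np.ndarray
    respondent_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.strata)
        for name in ("base", "poststrat", "nonresponse", "multiphone", "trim"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} factor has wrong length")
            if np.any(arr <= 0):
                raise ValueError(f"{name} factors must be positive")

    @classmethod
    def flat(cls, strata: Sequence[StratumKey],
             respondent_ids: Optional[np.ndarray] = None) -> "WeightSet":
        ones = np.ones(len(strata))
        return cls(tuple(strata), ones, ones.copy(), ones.copy(), ones.copy(),
                   ones.copy(), respondent_ids=respondent_ids)

    @property
    def n(self) -> int:
        return len(self.strata)

    @property
    def weights(self) -> np.ndarray:
        return self.base * self.poststrat * self.nonresponse * self.multiphone * self.trim

    @property
    def cv(self) -> float:
        return cv_of_weights(self)

    @property
    def deff(self) -> float:
        return design_effect(self)

    @property
    def effective_n(self) -> float:
        return effective_sample_size(self)

    def normalized(self) -> "WeightSet":
        """Rescale so weights average 1 (cosmetic: all diagnostics are
        scale-invariant)."""
        return replace(self, base=self.base / self.weights.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"respondent_id": (self.respondent_ids if self.respondent_ids is not None
                               else np.arange(self.n)),
             "stratum": ["|".join(k) for k in self.strata],
             "base": self.base, "poststrat": self.poststrat,
             "nonresponse": self.nonresponse, "multiphone": self.multiphone,
             "trim": self.trim, "final_weight": self.weights})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def diagnostics(self) -> Dict[str, float]:
        w = self.weights
        return {"n": self.n, "cv_wt": self.cv, "deff_wt": self.deff,
                "effective_n": self.effective_n,
                "min_weight": float(w.min()), "max_weight": float(w.max())}


def poststratification_weights(sample_strata: Sequence[StratumKey],
                               reference: ReferenceDistribution,
                               respondent_ids: Optional[np.ndarray] = None) -> WeightSet:
    """Weight each respondent by population share over sample share of their
    stratum, so weighted strata proportions equal the reference."""
    if len(sample_strata) == 0:
        raise ValueError("empty sample")
    counts = Counter(sample_strata)
    n = len(sample_strata)
    factors: Dict[StratumKey, float] = {}
    for key, c in counts.items():
        if key not in reference or reference[key] <= 0:
            raise KeyError(f"sampled stratum {key} absent from the reference distribution")
        factors[key] = reference[key] / (c / n)
    ws = WeightSet.flat(sample_strata, respondent_ids=respondent_ids)
    return replace(ws, poststrat=np.array([factors[k] for k in sample_strata]))


def nonresponse_adjustment(weights: WeightSet,
                           table: Mapping[StratumKey, float]) -> WeightSet:
    """Multiply each weight by R = 1/(1-f) for the respondent's group."""
    r = np.empty(weights.n)
    for i, key in enumerate(weights.strata):
        if key not in table:
            raise KeyError(f"no nonresponse rate for group {key}")
        f = table[key]
        if not (0.0 <= f < 1.0):
            raise ValueError(f"nonresponse rate {f} for group {key} outside [0, 1)")
        r[i] = 1.0 / (1.0 - f)
    return replace(weights, nonresponse=weights.nonresponse * r)


def multiphone_adjustment(weights: WeightSet, phone_counts: Sequence[int]) -> WeightSet:
    """Multiply each weight by A = 1/T for a respondent owning T phones."""
    t = np.asarray(phone_counts, dtype=float)
    if t.shape != (weights.n,):
        raise ValueError("one phone count per respondent required")
    if np.any(t < 1):
        raise ValueError("phone counts must be >= 1 for sampled respondents")
    return replace(weights, multiphone=weights.multiphone / t)


# ---------------------------------------------------------------------------
# closed-form selection probabilities

@dataclass(frozen=True)
class SelectionScenario:
    """Inclusion-probability inputs: targeted n, phones per person, total phones."""

    n: int
    phones_per_person: int
    total_phones: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("targeted sample size must be >= 1")
        if self.phones_per_person < 1:
            raise ValueError("phones per person must be >= 1")
        if self.total_phones < self.phones_per_person:
            raise ValueError("total phones must be >= phones per person")


def selection_probability(scenario: SelectionScenario) -> float:
    """Individual inclusion probability (n x N_p) / N_T."""
    if scenario.total_phones == 0:
        raise ZeroDivisionError("no phones in population")
    return scenario.n * scenario.phones_per_person / scenario.total_phones


def relative_probability(s1: SelectionScenario, s2: SelectionScenario) -> float:
    """Inclusion-probability ratio of two owners in the same phone population."""
    if s1.total_phones != s2.total_phones:
        raise ValueError("scenarios must share the same total phone count")
    return selection_probability(s1) / selection_probability(s2)


# ---------------------------------------------------------------------------
# weight-variability diagnostics

def _as_weights(weights) -> np.ndarray:
    w = weights.weights if isinstance(weights, WeightSet) else np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("no weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w


def cv_of_weights(weights) -> float:
    """Coefficient of variation of the weights (population SD / mean)."""
    w = _as_weights(weights)
    return float(w.std(ddof=0) / w.mean())


def design_effect(weights) -> float:
    """Kish's weighting design effect, deff = 1 + CV^2."""
    return 1.0 + cv_of_weights(weights) ** 2


def design_effect_sum_form(weights) -> float:
    """The algebraically identical sum form n*sum(w^2)/(sum(w))^2."""
    w = _as_weights(weights)
    return float(w.size * np.sum(w ** 2) / np.sum(w) ** 2)


def effective_sample_size(weights) -> float:
    """SRS-equivalent sample size n / deff."""
    w = _as_weights(weights)
    return w.size / design_effect(w)


def trim_weights(weights: WeightSet, lower: float, upper: float) -> WeightSet:
    """Clip weights to [lower, upper], then rescale to preserve the weight
    total.  Never increases the CV; may bias estimates (that is the trade)."""
    if not (0 < lower <= upper):
        raise ValueError("need 0 < lower <= upper")
    w = weights.weights
    clipped = np.clip(w, lower, upper)
    rescale = w.sum() / clipped.sum()
    return replace(weights, trim=weights.trim * (clipped * rescale) / w)


@dataclass(frozen=True)
class WeightedEstimate:
    estimate: float
    variance: float
    se: float
    deff: float
    n: int
    effective_n: float


def weighted_estimate(outcomes: Sequence[float], weights: WeightSet) -> WeightedEstimate:
    """Hajek-weighted mean with Kish-inflated variance.

    The variance is the SRS variance of the outcomes times the weighting
    design effect — Kish's approximation, reported as such.
    """
    y = np.asarray(outcomes, dtype=float)
    w = weights.weights
    if y.shape != w.shape:
        raise ValueError("one outcome per respondent required")
    est = float(np.sum(w * y) / np.sum(w))
    deff = design_effect(w)
    var = float(y.var(ddof=0) / y.size * deff)
    return WeightedEstimate(estimate=est, variance=var, se=var ** 0.5,
                            deff=deff, n=int(y.size),
                            effective_n=y.size / deff)
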
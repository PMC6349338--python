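"""Ensemble agreement statistics.

Model outputs (selected fishing mortalities, or yearly performance
indicators) are expressed as relative changes against the 2011-2013
reference and binned into six categories:

1. decrease by more than 20 %
2. decrease by 10-20 %
3. change within +/- 10 %
4. increase by 10-20 %
5. increase by more than 20 %
6. no information (the model does not constrain the quantity)

The A index of a tally with N cases, N_j of which fall into category j, is

    A = sum_j N_j (N_j - 1) / (N (N - 1)),

the probability that two cases drawn without replacement share a category:
1 for perfect agreement, 0 when every case differs.  Cases are enumerated
over all model variants and environmental combinations (and, for
indicators, over the 13 evaluation years 2020-2032).  The complementary
quantitative measure is the inverse coefficient of variation, |mean|/sd,
computed over the numeric outputs only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DataError, DomainError, UndefinedIndexError

__all__ = [
    "NO_INFORMATION",
    "N_CATEGORIES",
    "AgreementTally",
    "categorize",
    "a_index",
    "build_tally",
    "inverse_cv",
    "aggregate_agreement",
]

logger = logging.getLogger(__name__)

N_CATEGORIES = 6
#: Category code reserved for missing / uninformative outputs.
NO_INFORMATION = 6


def categorize(relative_change: Optional[float]) -> int:
    """Bin a relative change into categories 1-5; ``None`` maps to 6.

    Boundaries: |x| <= 0.10 is category 3; the 0.20 boundaries belong to
    categories 2 and 4 (so x = -0.20 is a 10-20 % decrease, not a >20 % one).
    """
    if relative_change is None:
        return NO_INFORMATION
    x = float(relative_change)
    if math.isnan(x) or math.isinf(x):
        raise DomainError(f"relative change must be finite, got {x}")
    if x < -0.20:
        return 1
    if x < -0.10:
        return 2
    if x <= 0.10:
        return 3
    if x <= 0.20:
        return 4
    return 5


@dataclass(frozen=True)
class AgreementTally:
    """Category counts N_j and their total N for one item."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CATEGORIES:
            raise DataError(f"tally needs {N_CATEGORIES} category counts")
        if any(c < 0 for c in self.counts):
            raise DataError("category counts must be >= 0")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_categories(cls, categories: Iterable[int]) -> "AgreementTally":
        counts = [0] * N_CATEGORIES
        for c in categories:
            if not 1 <= int(c) <= N_CATEGORIES:
                raise DataError(f"category code {c} outside 1..{N_CATEGORIES}")
            counts[int(c) - 1] += 1
        return cls(tuple(counts))


def a_index(tally: AgreementTally, include_no_information: bool = True) -> float:
    """Pair-concordance agreement of a tally, in [0, 1].

    With ``include_no_information`` (the default) category 6 counts as an
    ordinary category, so two "no information" outputs agree with each
    other; setting it to ``False`` drops those cases before computing the
    index.  Undefined for fewer than two cases.
    """
    counts = np.asarray(tally.counts, dtype=float)
    if not include_no_information:
        counts = counts[: NO_INFORMATION - 1]
    n = counts.sum()
    if n < 2:
        raise UndefinedIndexError(f"A index needs at least 2 cases, got {int(n)}")
    return float(np.sum(counts * (counts - 1.0)) / (n * (n - 1.0)))


def build_tally(scenario_outputs: Sequence, target: str = "f_advice") -> AgreementTally:
    """Tally categorised outputs across ensemble cases.

    For ``target="f_advice"`` each element of ``scenario_outputs`` is one
    case's relative F change (or ``None``), one case per model variant and
    environmental combination.  For ``target="indicator"`` each element is
    that case's sequence of yearly relative changes over the evaluation
    window (all cases must supply equally many years), so the tally size is
    cases x years.
    """
    if target == "f_advice":
        values = list(scenario_outputs)
    elif target == "indicator":
        lengths = {len(tuple(case)) for case in scenario_outputs}
        if len(lengths) > 1:
            raise DataError(f"ragged indicator outputs: case lengths {sorted(lengths)}")
        values = [v for case in scenario_outputs for v in case]
    else:
        raise DataError(f"unknown tally target {target!r}")
    return AgreementTally.from_categories(categorize(v) for v in values)


def inverse_cv(values: Iterable[Optional[float]]) -> Optional[float]:
    """Inverse coefficient of variation |mean|/sd of the numeric outputs.

    ``None``/NaN entries (no information) are excluded first.  Returns
    ``math.inf`` as the perfect-agreement marker when the dispersion is
    zero, and ``None`` (undefined) when fewer than two numeric values
    remain.  Uses the sample (n-1) standard deviation; the absolute mean
    keeps the measure defined for negative-profit indicators.
    """
    nums = [float(v) for v in values if v is not None and not math.isnan(float(v))]
    if len(nums) < 2:
        return None
    arr = np.asarray(nums)
    sd = float(arr.std(ddof=1))
    # dispersion at the level of float rounding noise is zero dispersion
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(arr)))):
        return math.inf
    return abs(float(arr.mean())) / sd


def aggregate_agreement(per_item_values: Mapping[str, Optional[float]]) -> float:
    """Scenario-level agreement: arithmetic mean over items.

    Items are the three stocks (for F advice) or the six performance
    indicators.  Undefined items (``None``) are dropped with a logged
    count; a perfect-agreement marker (``inf``) propagates into the mean.
    Raises if every item is undefined.
    """
    defined = {k: v for k, v in per_item_values.items() if v is not None}
    dropped = len(per_item_values) - len(defined)
    if dropped:
        logger.info("aggregate_agreement: dropped %d undefined item(s)", dropped)
    if not defined:
        raise UndefinedIndexError("all items undefined; no agreement value")
    return float(np.mean(list(defined.values())))
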
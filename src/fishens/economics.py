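"""Bio-economic layer: fleet allocation, yearly profits and net present value.

Three fleet segments are modelled: bottom trawlers (BT) and gillnetters /
passive gears (GN) fishing cod, and pelagic trawlers (PT) fishing herring
and sprat.  Profit per year is landings times price minus costs; cod costs
scale with fishing mortality, clupeid costs with landed tonnage.  All
catches are treated as landings.  Gillnet revenue can be degraded by seal
damage (a fraction of the passive-gear cod landings is discarded as
seal-damaged, increasing with seal abundance).

Prices and costs are in relative currency units; only differences between
management scenarios are meaningful, not absolute profit levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "EconomicParams",
    "ProfitRecord",
    "allocate_cod_catch",
    "seal_damage_fraction",
    "yearly_profit",
    "npv",
    "DEFAULT_ECONOMICS",
]

FLEETS = ("BT", "GN", "PT")


@dataclass(frozen=True)
class EconomicParams:
    """Prices, costs and the discounting/seal-damage settings.

    ``price`` is currency per tonne by stock; ``cod_cost_coeff`` is currency
    per unit of cod F for each cod fleet; ``clupeid_cost_coeff`` is currency
    per tonne of clupeids landed.  ``cod_fleet_split`` is the BT share of the
    cod catch (the GN share is the complement).  ``seal_damage_coeff`` is the
    fraction of GN landings lost per unit of relative seal biomass, capped
    at 1.
    """

    price: Mapping[str, float] = field(
        default_factory=lambda: {"cod": 1.5, "herring": 0.3, "sprat": 0.2}
    )
    cod_cost_coeff: Mapping[str, float] = field(
        default_factory=lambda: {"BT": 0.5, "GN": 0.1}
    )
    clupeid_cost_coeff: float = 0.1
    cod_fleet_split: float = 0.83
    discount_rate: float = 0.03
    seal_damage_coeff: float = 0.02
    seal_damage_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.cod_fleet_split <= 1.0:
            raise DomainError(f"cod_fleet_split must be in [0,1], got {self.cod_fleet_split}")
        if self.discount_rate < 0:
            raise DomainError("discount_rate must be >= 0")
        if any(v < 0 for v in self.price.values()):
            raise DomainError("prices must be >= 0")
        if any(v < 0 for v in self.cod_cost_coeff.values()) or self.clupeid_cost_coeff < 0:
            raise DomainError("cost coefficients must be >= 0")
        if self.seal_damage_coeff < 0:
            raise DomainError("seal_damage_coeff must be >= 0")

    def without_seal_damage(self) -> "EconomicParams":
        return replace(self, seal_damage_enabled=False)


DEFAULT_ECONOMICS = EconomicParams()


@dataclass(frozen=True)
class ProfitRecord:
    """Profit of each fleet segment for one year; total is their sum."""

    profit_bt: float
    profit_gn: float
    profit_pt: float

    @property
    def profit_total(self) -> float:
        return self.profit_bt + self.profit_gn + self.profit_pt


def allocate_cod_catch(total_catch, split: float = 0.83):
    """Split the cod catch between bottom trawls and gillnets.

    Returns ``(BT, GN) = (split * total, total - BT)``; computing GN as the
    remainder conserves the total catch.  Accepts scalars or arrays.
    """
    total = np.asarray(total_catch, dtype=float)
    if np.any(total < 0):
        raise DomainError("cod catch must be >= 0")
    bt = split * total
    gn = total - bt
    if total.ndim == 0:
        return float(bt), float(gn)
    return bt, gn


def seal_damage_fraction(seal_biomass, params: EconomicParams):
    """Fraction of gillnet landings discarded as seal-damaged, in [0, 1]."""
    b = np.asarray(seal_biomass, dtype=float)
    if np.any(b < 0):
        raise DomainError("seal biomass must be >= 0")
    if not params.seal_damage_enabled:
        return np.zeros_like(b) if b.ndim else 0.0
    d = np.minimum(1.0, params.seal_damage_coeff * b)
    return d if b.ndim else float(d)


def yearly_profit(
    landings: Mapping[str, float],
    f_cod: float,
    seal_biomass: float,
    params: EconomicParams = DEFAULT_ECONOMICS,
) -> ProfitRecord:
    """Profit of each fleet segment for one year.

    ``landings`` maps stock name to tonnes landed that year.  Cod landings
    are split 83/17 (by default) between BT and GN; each cod fleet pays
    ``f_cod`` times its cost coefficient.  The pelagic-trawl profit is the
    sum of the herring and sprat profits, each landings*(price - unit cost).
    """
    for k, v in landings.items():
        if v < 0:
            raise DomainError(f"negative landings for {k}")
    if f_cod < 0:
        raise DomainError("cod F must be >= 0")
    l_bt, l_gn = allocate_cod_catch(landings.get("cod", 0.0), params.cod_fleet_split)
    damage = seal_damage_fraction(seal_biomass, params)
    p_c = params.price["cod"]
    profit_bt = p_c * l_bt - f_cod * params.cod_cost_coeff["BT"]
    profit_gn = p_c * l_gn * (1.0 - damage) - f_cod * params.cod_cost_coeff["GN"]
    profit_pt = sum(
        (params.price[s] - params.clupeid_cost_coeff) * landings.get(s, 0.0)
        for s in ("herring", "sprat")
    )
    return ProfitRecord(profit_bt=profit_bt, profit_gn=profit_gn, profit_pt=profit_pt)


def npv(profit_series, discount_rate: float, base_year: int) -> float:
    """Net present value of a year-indexed profit stream.

    ``profit_series`` is a mapping or :class:`pandas.Series` indexed by
    calendar year.  Each year's profit is discounted by
    ``(1 + rate)^(year - base_year)``; the base year itself is undiscounted.
    An empty series returns 0 with a warning.
    """
    if discount_rate < 0:
        raise DomainError("discount rate must be >= 0")
    series = pd.Series(dict(profit_series)) if not isinstance(profit_series, pd.Series) else profit_series
    if series.empty:
        warnings.warn("npv of an empty profit series is 0", stacklevel=2)
        return 0.0
    years = series.index.to_numpy(dtype=float)
    factors = (1.0 + discount_rate) ** (years - float(base_year))
    return float(np.sum(series.to_numpy(dtype=float) / factors))
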
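"""Scenario engine: F grids, objectives, optimal-F selection and indicators.

The management experiment is a multi-factorial design: every combination
of per-stock fishing mortalities from a grid (default 0-1.4) is simulated
under every environmental scenario and model variant, and for each of five
management scenarios the F vector satisfying the scenario objective is
selected from the grid:

* **PE** (Piscivore Exploitation) -- maximise the discounted cumulative
  profit of the cod fleets (bottom trawls + gillnets).
* **FE** (Forage Fish Exploitation) -- maximise the discounted cumulative
  profit of the pelagic trawlers.
* **PF** (Portfolio Fishery) -- maximise total discounted fishery profit.
* **PR** (Piscivore Recovery) -- maximise the 2028-2032 mean cod:clupeid
  biomass ratio subject to herring and sprat SSB staying above B_lim.
* **SQ** (Status Quo) -- no optimisation; Fs fixed at the 2011-2013 means.

If, at the optimum, the objective is flat along one F dimension (relative
range below a tolerance), that stock's F is reported as "no information":
the model does not constrain it.  Performance indicators are yearly
relative changes of SSB and fleet profits against the 2011-2013 reference
means, evaluated over 2020-2032 (the first six projection years are
discarded as a transition period).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import GridSim, SimulationResult, simulate_grid
from .economics import DEFAULT_ECONOMICS, EconomicParams, allocate_cod_catch, seal_damage_fraction
from .errors import ConfigurationError, DataError, DomainError
from .forcing import BaselineState, ForcingScenario, STOCKS
from .structures import ModelStructure

__all__ = [
    "INDICATORS",
    "DEFAULT_F_RANGE",
    "DEFAULT_F_STEP",
    "DEFAULT_BLIM",
    "FishingRegime",
    "ScenarioDefinition",
    "SCENARIOS",
    "Selection",
    "IndicatorSeries",
    "GridEvaluation",
    "build_f_grid",
    "grid_matrix",
    "clip_regimes",
    "cumulative_yield",
    "evaluate_grid",
    "profit_frame",
    "evaluate_objective",
    "objective_values",
    "select_optimal",
    "performance_indicators",
    "INFEASIBLE",
]

INDICATORS = ("ssb_cod", "ssb_herring", "ssb_sprat", "profit_bt", "profit_pt", "profit_total")
DEFAULT_F_RANGE = (0.0, 1.4)
DEFAULT_F_STEP = 0.2
#: Minimum safe SSB for the Piscivore Recovery constraint (relative units).
DEFAULT_BLIM = {"herring": 3.5, "sprat": 4.0}
#: Sentinel returned by evaluate_objective when the PR constraints fail.
INFEASIBLE = None

_EVAL_YEARS = np.arange(2020, 2033)
_PR_WINDOW = (2028, 2032)


@dataclass(frozen=True)
class FishingRegime:
    """A constant-over-projection F vector, one entry per stock."""

    f: Mapping[str, float]

    def __post_init__(self) -> None:
        for s in STOCKS:
            if s not in self.f:
                raise ConfigurationError(f"regime missing F for {s}")
            if self.f[s] < 0:
                raise DomainError(f"F for {s} must be >= 0")

    def as_row(self) -> np.ndarray:
        return np.asarray([self.f[s] for s in STOCKS], dtype=float)


@dataclass(frozen=True)
class ScenarioDefinition:
    """Name and objective settings of one management scenario."""

    name: str
    description: str
    blim: Mapping[str, float] = field(default_factory=dict)
    window: tuple[int, int] = _PR_WINDOW

    @property
    def optimises(self) -> bool:
        return self.name != "SQ"


SCENARIOS: dict[str, ScenarioDefinition] = {
    "PE": ScenarioDefinition("PE", "maximise NPV of cod-fleet (BT+GN) profits"),
    "FE": ScenarioDefinition("FE", "maximise NPV of pelagic-trawl profits"),
    "PF": ScenarioDefinition("PF", "maximise NPV of total fishery profits"),
    "PR": ScenarioDefinition(
        "PR",
        "maximise 2028-2032 mean cod:clupeid biomass ratio with SSB > Blim",
        blim=dict(DEFAULT_BLIM),
    ),
    "SQ": ScenarioDefinition("SQ", "continue the 2011-2013 fishing mortalities"),
}


def build_f_grid(
    ranges: Mapping[str, tuple[float, float]] | None = None,
    resolution: float = DEFAULT_F_STEP,
) -> list[FishingRegime]:
    """Cartesian product of per-stock F values, in lexicographic stock order.

    Each stock's values run from the lower to the upper bound inclusive in
    steps of ``resolution`` (e.g. 0-1.4 at 0.2 gives 8 values per stock and
    8^3 = 512 regimes).
    """
    if resolution <= 0:
        raise ConfigurationError("grid resolution must be > 0")
    ranges = {s: DEFAULT_F_RANGE for s in STOCKS} if ranges is None else dict(ranges)
    axes = []
    for s in STOCKS:
        lo, hi = ranges[s]
        if hi < lo:
            raise ConfigurationError(f"empty F range for {s}: ({lo}, {hi})")
        n = int(np.floor((hi - lo) / resolution + 1e-9)) + 1
        axes.append(np.round(lo + resolution * np.arange(n), 10))
    return [
        FishingRegime(f=dict(zip(STOCKS, combo)))
        for combo in itertools.product(*axes)
    ]


def grid_matrix(regimes: Sequence[FishingRegime]) -> np.ndarray:
    if not regimes:
        raise ConfigurationError("empty regime list")
    return np.vstack([r.as_row() for r in regimes])


def clip_regimes(
    regimes: Sequence[FishingRegime], structure: ModelStructure
) -> list[FishingRegime]:
    """Drop regimes outside the variant's F convention domain.

    Harvest-rate variants cannot remove more than the whole annual biomass,
    so grid points with any F > 1 are dropped for them; instantaneous-F
    variants keep the full grid.
    """
    fmax = structure.f_max
    kept = [r for r in regimes if all(r.f[s] <= fmax for s in STOCKS)]
    if not kept:
        raise ConfigurationError(f"no regime admissible under {structure.f_convention}")
    return kept


def cumulative_yield(result: SimulationResult, stock: str, years=None) -> float:
    """Summed catches of one stock over the projection (default: all years)."""
    if years is not None:
        missing = set(np.asarray(years, dtype=int)) - set(result.years.tolist())
        if missing:
            raise DataError(f"result is missing years {sorted(missing)}")
        mask = np.isin(result.years, np.asarray(years, dtype=int))
    else:
        mask = np.ones_like(result.years, dtype=bool)
    return float(np.sum(result.catch[stock][mask]))


# ---------------------------------------------------------------------------
# grid evaluation: simulation + economics
# ---------------------------------------------------------------------------

def _profit_arrays(
    sim: GridSim, seal_series: np.ndarray, econ: EconomicParams
) -> dict[str, np.ndarray]:
    """Undiscounted yearly profit per fleet, year by regime."""
    bt_land, gn_land = allocate_cod_catch(sim.catch["cod"], econ.cod_fleet_split)
    # seal series is regime-independent within a run
    damage = np.asarray(
        [seal_damage_fraction(float(b), econ) for b in seal_series], dtype=float
    )[:, None]
    f_cod = sim.f[:, STOCKS.index("cod")][None, :]
    p_c = econ.price["cod"]
    profit_bt = p_c * bt_land - f_cod * econ.cod_cost_coeff["BT"]
    profit_gn = p_c * gn_land * (1.0 - damage) - f_cod * econ.cod_cost_coeff["GN"]
    profit_pt = (econ.price["herring"] - econ.clupeid_cost_coeff) * sim.catch["herring"] + (
        econ.price["sprat"] - econ.clupeid_cost_coeff
    ) * sim.catch["sprat"]
    return {
        "profit_bt": profit_bt,
        "profit_gn": profit_gn,
        "profit_pt": profit_pt,
        "profit_total": profit_bt + profit_gn + profit_pt,
    }


@dataclass(frozen=True)
class GridEvaluation:
    """One variant x forcing combination evaluated over a full F grid."""

    structure: ModelStructure
    forcing: ForcingScenario
    baseline: BaselineState
    econ: EconomicParams
    regimes: list[FishingRegime]
    sim: GridSim
    profits: Mapping[str, np.ndarray]  # fleet profit, (T, n)

    @property
    def f(self) -> np.ndarray:
        return self.sim.f

    def cumulative_yields(self, stock: str) -> np.ndarray:
        return self.sim.catch[stock].sum(axis=0)

    def npv_of(self, key: str) -> np.ndarray:
        """NPV of a profit array over the projection, per regime."""
        years = self.sim.years.astype(float)
        factors = (1.0 + self.econ.discount_rate) ** (years - years[0])
        return (self.profits[key] / factors[:, None]).sum(axis=0)

    def extract_profit_frame(self, index: int) -> pd.DataFrame:
        data = {k: v[:, index] for k, v in self.profits.items()}
        return pd.DataFrame(data, index=pd.Index(self.sim.years, name="year"))


def evaluate_grid(
    structure: ModelStructure,
    regimes: Sequence[FishingRegime],
    forcing: ForcingScenario,
    baseline: BaselineState,
    econ: EconomicParams = DEFAULT_ECONOMICS,
) -> GridEvaluation:
    """Simulate every regime and attach fleet profits.

    Seal damage on the passive gear is applied only when the variant itself
    models seals; for seal-free variants the damage channel is disabled.
    """
    regimes = list(regimes)
    if structure.seal.form == "none":
        econ = econ.without_seal_damage()
    sim = simulate_grid(structure, grid_matrix(regimes), forcing, baseline)
    profits = _profit_arrays(sim, forcing.seal_biomass.to_numpy(dtype=float), econ)
    return GridEvaluation(
        structure=structure,
        forcing=forcing,
        baseline=baseline,
        econ=econ,
        regimes=regimes,
        sim=sim,
        profits=profits,
    )


def profit_frame(
    result: SimulationResult,
    seal_biomass: pd.Series,
    econ: EconomicParams = DEFAULT_ECONOMICS,
) -> pd.DataFrame:
    """Year-indexed undiscounted profits per fleet for a single run."""
    bt_land, gn_land = allocate_cod_catch(result.catch["cod"], econ.cod_fleet_split)
    damage = np.asarray(
        [seal_damage_fraction(float(seal_biomass.loc[y]), econ) for y in result.years]
    )
    f_cod = result.f["cod"]
    p_c = econ.price["cod"]
    profit_bt = p_c * bt_land - f_cod * econ.cod_cost_coeff["BT"]
    profit_gn = p_c * gn_land * (1.0 - damage) - f_cod * econ.cod_cost_coeff["GN"]
    profit_pt = (econ.price["herring"] - econ.clupeid_cost_coeff) * result.catch["herring"] + (
        econ.price["sprat"] - econ.clupeid_cost_coeff
    ) * result.catch["sprat"]
    return pd.DataFrame(
        {
            "profit_bt": profit_bt,
            "profit_gn": profit_gn,
            "profit_pt": profit_pt,
            "profit_total": profit_bt + profit_gn + profit_pt,
        },
        index=pd.Index(result.years, name="year"),
    )


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def objective_values(ge: GridEvaluation, scenario: ScenarioDefinition) -> np.ndarray:
    """Objective value per regime; NaN marks infeasible (PR constraints)."""
    if scenario.name == "PE":
        return ge.npv_of("profit_bt") + ge.npv_of("profit_gn")
    if scenario.name == "FE":
        return ge.npv_of("profit_pt")
    if scenario.name == "PF":
        return ge.npv_of("profit_total")
    if scenario.name == "PR":
        lo, hi = scenario.window
        mask = (ge.sim.years >= lo) & (ge.sim.years <= hi)
        b_c = ge.sim.biomass("cod")[mask]
        b_clup = ge.sim.biomass("herring")[mask] + ge.sim.biomass("sprat")[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(b_clup > 0, b_c / np.where(b_clup > 0, b_clup, 1.0), np.nan)
        vals = ratio.mean(axis=0)
        ssb_h = ge.sim.ssb["herring"][mask].mean(axis=0)
        ssb_s = ge.sim.ssb["sprat"][mask].mean(axis=0)
        ok = (ssb_h > scenario.blim["herring"]) & (ssb_s > scenario.blim["sprat"])
        return np.where(ok, vals, np.nan)
    raise ConfigurationError(f"scenario {scenario.name!r} defines no objective")


def evaluate_objective(
    result: SimulationResult,
    profits: pd.DataFrame,
    scenario: ScenarioDefinition,
    discount_rate: float = DEFAULT_ECONOMICS.discount_rate,
) -> Optional[float]:
    """Objective value of a single run, or ``None`` (infeasible) for PR.

    ``profits`` is the undiscounted per-fleet frame of :func:`profit_frame`;
    monetary objectives discount it to NPV at ``discount_rate`` with the
    first projection year as base.
    """
    years = result.years.astype(float)
    factors = (1.0 + discount_rate) ** (years - years[0])
    if scenario.name == "PE":
        return float(((profits["profit_bt"] + profits["profit_gn"]) / factors).sum())
    if scenario.name == "FE":
        return float((profits["profit_pt"] / factors).sum())
    if scenario.name == "PF":
        return float((profits["profit_total"] / factors).sum())
    if scenario.name == "PR":
        lo, hi = scenario.window
        mask = (result.years >= lo) & (result.years <= hi)
        b_clup = result.biomass("herring")[mask] + result.biomass("sprat")[mask]
        if np.any(b_clup <= 0):
            return INFEASIBLE
        ratio = float((result.biomass("cod")[mask] / b_clup).mean())
        if float(result.ssb["herring"][mask].mean()) <= scenario.blim["herring"]:
            return INFEASIBLE
        if float(result.ssb["sprat"][mask].mean()) <= scenario.blim["sprat"]:
            return INFEASIBLE
        return ratio
    raise ConfigurationError(f"scenario {scenario.name!r} defines no objective")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Outcome of optimal-F selection for one scenario and ensemble case.

    ``f[stock]`` is ``None`` when the model provides no information about
    that stock's F; ``feasible`` is False when no regime satisfied the
    scenario's constraints at all.
    """

    scenario: str
    f: Mapping[str, Optional[float]]
    no_information: frozenset[str] = frozenset()
    feasible: bool = True
    objective: Optional[float] = None
    index: Optional[int] = None


def select_optimal(
    ge: GridEvaluation,
    scenario: ScenarioDefinition,
    insensitivity_tol: float = 1e-6,
) -> Selection:
    """Grid-argmax of the scenario objective with flat-dimension detection.

    Ties are broken toward the lexicographically smallest F vector in
    (cod, herring, sprat) order.  A dimension along which the objective's
    relative range (at the optimum of the other dimensions) falls below
    ``insensitivity_tol`` is reported as "no information"; dimensions with
    a single grid value cannot be assessed and are reported as informative.
    The Status Quo scenario skips optimisation and returns the baseline
    reference Fs exactly.
    """
    if scenario.name == "SQ":
        return Selection(
            scenario="SQ", f={s: float(ge.baseline.reference_F[s]) for s in STOCKS}
        )
    vals = objective_values(ge, scenario)
    finite = np.isfinite(vals)
    if not np.any(finite):
        return Selection(
            scenario=scenario.name,
            f={s: None for s in STOCKS},
            no_information=frozenset(STOCKS),
            feasible=False,
        )
    vmax = np.max(vals[finite])
    ties = np.flatnonzero(finite & (vals == vmax))
    best = min(ties, key=lambda i: tuple(ge.f[i]))
    f_best = ge.f[best]

    no_info: set[str] = set()
    scale = max(abs(vmax), 1e-12)
    for d, stock in enumerate(STOCKS):
        others = [k for k in range(len(STOCKS)) if k != d]
        mask = np.all(ge.f[:, others] == f_best[others], axis=1)
        slice_vals = vals[mask & finite]
        if len(np.unique(ge.f[mask, d])) < 2 or slice_vals.size < 2:
            continue
        rel_range = (slice_vals.max() - slice_vals.min()) / scale
        if rel_range < insensitivity_tol:
            no_info.add(stock)

    f_sel = {
        s: (None if s in no_info else float(f_best[i])) for i, s in enumerate(STOCKS)
    }
    return Selection(
        scenario=scenario.name,
        f=f_sel,
        no_information=frozenset(no_info),
        objective=float(vmax),
        index=int(best),
    )


# ---------------------------------------------------------------------------
# performance indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorSeries:
    """Yearly relative changes (2020-2032) of the six indicators.

    ``frame`` is a 13-row year-indexed table; columns listed in
    ``no_information`` carry NaN and mean the model does not constrain that
    indicator for this case (missing selected F, zero reference, or an
    infeasible scenario).
    """

    frame: pd.DataFrame
    no_information: frozenset[str] = frozenset()

    def values_for(self, indicator: str) -> list[Optional[float]]:
        if indicator in self.no_information:
            return [None] * len(self.frame)
        return [float(v) for v in self.frame[indicator]]


def performance_indicators(
    result: SimulationResult,
    profits: pd.DataFrame,
    reference_means: Mapping[str, float],
    years: np.ndarray = _EVAL_YEARS,
) -> IndicatorSeries:
    """Relative change of each indicator vs. its 2011-2013 reference mean.

    ``(X_y - ref) / |ref|`` per evaluation year; indicators with a zero
    reference are flagged "no information".
    """
    years = np.asarray(years, dtype=int)
    missing = set(years.tolist()) - set(result.years.tolist())
    if missing:
        raise DataError(f"result is missing evaluation years {sorted(missing)}")
    mask = np.isin(result.years, years)
    raw = {
        "ssb_cod": result.ssb["cod"][mask],
        "ssb_herring": result.ssb["herring"][mask],
        "ssb_sprat": result.ssb["sprat"][mask],
        "profit_bt": profits["profit_bt"].to_numpy()[mask],
        "profit_pt": profits["profit_pt"].to_numpy()[mask],
        "profit_total": profits["profit_total"].to_numpy()[mask],
    }
    no_info = set()
    cols = {}
    for ind in INDICATORS:
        ref = float(reference_means[ind])
        if ref == 0.0:
            no_info.add(ind)
            cols[ind] = np.full(len(years), np.nan)
        else:
            cols[ind] = (raw[ind] - ref) / abs(ref)
    frame = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return IndicatorSeries(frame=frame, no_information=frozenset(no_info))
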
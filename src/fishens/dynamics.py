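"""Multispecies biomass-dynamics simulator.

Each stock is represented by an adult and a juvenile biomass pool.  Within
a simulated year the order of operations is fixed and results depend on it:

1. **Rates** -- predation, seal and feedback terms are evaluated at the
   beginning-of-year state.
2. **Production** -- the adult pool grows by its (possibly environment-,
   density-, food- and competition-modified) surplus-production coefficient
   and receives last year's surviving juveniles; spawning produces a new
   juvenile cohort from beginning-of-year SSB.
3. **Mortality partition** -- fishing and natural mortality are applied.
   Under the ``harvest_rate`` convention the catch is F times the
   beginning-of-year adult biomass (annual catch/biomass), removed after
   production, and natural mortality acts on the remainder as exp(-M).
   Under the ``instantaneous`` convention fishing and natural mortality act
   concurrently through the Baranov catch equation,
   C = F/Z * (1 - exp(-Z)) * B with Z = F + M.

SSB is the adult-pool biomass.  Adult biomasses are floored at zero with a
collapse flag so that extreme corners of the F grid always complete.

The implementation is vectorised over fishing regimes: a whole F grid is
simulated in one pass with numpy arrays, and the scalar :func:`step` /
:func:`simulate` API is the one-regime special case of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ForcingError, RegimeError
from .forcing import BaselineState, ForcingScenario, STOCKS
from .structures import ModelStructure, Predation, SealPredation

__all__ = [
    "StockState",
    "ForcingYear",
    "StepRecord",
    "SimulationResult",
    "GridSim",
    "recruitment_ricker",
    "recruitment_beverton_holt",
    "recruitment_hockey_stick",
    "predation_mortality",
    "seal_mortality",
    "step",
    "simulate",
    "simulate_grid",
]

#: Biomass below this is treated as a collapsed (extinct) pool.
COLLAPSE_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# stock-recruitment relationships
# ---------------------------------------------------------------------------

def _check_ssb(ssb):
    ssb = np.asarray(ssb, dtype=float)
    if np.any(ssb < 0):
        raise DomainError("spawning stock biomass must be >= 0")
    return ssb


def recruitment_ricker(ssb, a: float, b: float):
    """Ricker recruitment a*S*exp(-b*S): dome-shaped, peak a/(b*e) at S=1/b."""
    if a <= 0 or b <= 0:
        raise DomainError("Ricker parameters a, b must be > 0")
    s = _check_ssb(ssb)
    out = a * s * np.exp(-b * s)
    return float(out) if out.ndim == 0 else out


def recruitment_beverton_holt(ssb, a: float, b: float):
    """Beverton-Holt recruitment a*S/(b+S): monotone, asymptote a, half at S=b."""
    if a <= 0 or b <= 0:
        raise DomainError("Beverton-Holt parameters a, b must be > 0")
    s = _check_ssb(ssb)
    out = a * s / (b + s)
    return float(out) if out.ndim == 0 else out


def recruitment_hockey_stick(ssb, a: float, s_break: float):
    """Hockey-stick recruitment: linear up to the breakpoint, plateau a beyond."""
    if a <= 0 or s_break <= 0:
        raise DomainError("hockey-stick parameters a, s_break must be > 0")
    s = _check_ssb(ssb)
    out = a * np.minimum(s, s_break) / s_break
    return float(out) if out.ndim == 0 else out


def _recruit(spec, ssb):
    if spec.form == "none":
        return np.zeros_like(np.asarray(ssb, dtype=float))
    if spec.form == "ricker":
        return recruitment_ricker(ssb, spec.a, spec.b)
    if spec.form == "beverton_holt":
        return recruitment_beverton_holt(ssb, spec.a, spec.b)
    return recruitment_hockey_stick(ssb, spec.a, spec.s_break)


# ---------------------------------------------------------------------------
# predation and seal mortality
# ---------------------------------------------------------------------------

def predation_mortality(
    pred_biomass,
    prey_index: str,
    prey_biomasses: Mapping[str, object],
    form: str,
    params: Predation,
):
    """Predation mortality rate of one prey item caused by adult cod.

    ``prey_biomasses`` maps every prey item in ``params.prey`` to its
    biomass.  See :class:`~fishens.structures.Predation` for the two
    functional forms.  Accepts scalars or aligned arrays.
    """
    bp = np.asarray(pred_biomass, dtype=float)
    if np.any(bp < 0) or any(np.any(np.asarray(v) < 0) for v in prey_biomasses.values()):
        raise DomainError("biomasses must be >= 0")
    if form == "none" or prey_index not in params.prey:
        return np.zeros_like(bp) if bp.ndim else 0.0
    if form == "linear_pred_declining_prey":
        pool = params.pool_half_sat + sum(
            np.asarray(prey_biomasses[q], dtype=float) for q in params.prey
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(pool > 0, params.attack[prey_index] * bp / np.where(pool > 0, pool, 1.0),
                           params.guard_max)
        out = np.minimum(raw, params.guard_max)
    elif form == "saturating_pred":
        b_own = np.asarray(prey_biomasses[prey_index], dtype=float)
        a_half = params.avail_half_sat.get(prey_index, 0.0)
        avail = b_own / (a_half + b_own) if a_half > 0 else np.ones_like(b_own)
        avail = np.where(a_half + b_own > 0, avail, 0.0)
        out = params.max_rate[prey_index] * bp / (params.pred_half_sat + bp) * avail
        out = np.where(params.pred_half_sat + bp > 0, out, 0.0)
    else:
        raise DomainError(f"unknown predation form {form!r}")
    return float(out) if out.ndim == 0 else out


def seal_mortality(seal_biomass, prey_biomass, form: str, params: SealPredation, stock: str = "cod"):
    """Seal-induced mortality rate on one fish stock.

    ``linear`` is proportional to seal biomass (doubling seals doubles the
    rate); ``saturating`` is bounded above by the per-stock coefficient
    however large the seal population grows.
    """
    bs = np.asarray(seal_biomass, dtype=float)
    bf = np.asarray(prey_biomass, dtype=float)
    if np.any(bs < 0) or np.any(bf < 0):
        raise DomainError("biomasses must be >= 0")
    coeff = params.coeff.get(stock, 0.0)
    if form == "none" or coeff == 0.0:
        out = np.zeros_like(bs * bf)
        return float(out) if out.ndim == 0 else out
    half = params.prey_half_sat.get(stock, 1.0)
    phi = bf / (half + bf) if half > 0 else np.ones_like(bf)
    if form == "linear":
        out = coeff * bs * phi
    elif form == "saturating":
        out = coeff * bs / (params.seal_half_sat + bs) * phi
    else:
        raise DomainError(f"unknown seal predation form {form!r}")
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StockState:
    """Adult and juvenile biomass per stock; SSB is the adult pool."""

    adult: Mapping[str, float]
    juvenile: Mapping[str, float]

    def __post_init__(self) -> None:
        for s in STOCKS:
            if self.adult[s] < 0 or self.juvenile[s] < 0:
                raise DomainError(f"negative biomass for {s}")

    @property
    def ssb(self) -> dict[str, float]:
        return dict(self.adult)

    @classmethod
    def from_baseline(cls, baseline: BaselineState) -> "StockState":
        return cls(adult=dict(baseline.adult), juvenile=dict(baseline.juvenile))


@dataclass(frozen=True)
class ForcingYear:
    """One year's slice of a forcing scenario."""

    year: int
    growth_mult: Mapping[str, float]
    recruit_mult: Mapping[str, float]
    seal_biomass: float

    def validate(self) -> None:
        vals = [self.seal_biomass, *self.growth_mult.values(), *self.recruit_mult.values()]
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ForcingError(f"forcing for year {self.year} must be finite and > 0")

    @classmethod
    def from_scenario(cls, forcing: ForcingScenario, year: int) -> "ForcingYear":
        return cls(
            year=int(year),
            growth_mult={s: float(forcing.growth_multiplier.loc[year, s]) for s in STOCKS},
            recruit_mult={s: float(forcing.recruit_multiplier.loc[year, s]) for s in STOCKS},
            seal_biomass=float(forcing.seal_biomass.loc[year]),
        )


@dataclass(frozen=True)
class StepRecord:
    """Per-year diagnostics for one step: catch, mortality rates, collapses."""

    year: int
    ssb: Mapping[str, float]
    catch: Mapping[str, float]
    m2: Mapping[str, float]
    seal_rate: Mapping[str, float]
    collapsed: Mapping[str, bool]


# ---------------------------------------------------------------------------
# vectorised core
# ---------------------------------------------------------------------------

def _validate_f(f_arrays: Mapping[str, np.ndarray], structure: ModelStructure) -> None:
    for s in STOCKS:
        f = f_arrays[s]
        if np.any(~np.isfinite(f)) or np.any(f < 0):
            raise RegimeError(f"F for {s} must be finite and >= 0")
        if np.any(f > structure.f_max):
            raise RegimeError(
                f"F={np.max(f):g} for {s} exceeds the {structure.f_convention} "
                f"convention's maximum of {structure.f_max:g}"
            )


def _advance(
    adult: dict[str, np.ndarray],
    juv: dict[str, np.ndarray],
    f_arrays: Mapping[str, np.ndarray],
    fy: ForcingYear,
    st: ModelStructure,
):
    """One year for every regime at once.  Returns (adult', juv', diagnostics)."""
    b_cod = adult["cod"]
    prey_b = {"herring": adult["herring"], "sprat": adult["sprat"], "juv_cod": juv["cod"]}
    m2 = {
        p: predation_mortality(b_cod, p, prey_b, st.predation.form, st.predation)
        for p in st.predation.prey
    }
    seal_rate = {
        s: seal_mortality(fy.seal_biomass, adult[s], st.seal.form, st.seal, stock=s)
        for s in STOCKS
    }

    if st.clupeid_competition:
        comp = 1.0 / (1.0 + st.competition_coeff * (adult["herring"] + adult["sprat"]))
    else:
        comp = 1.0
    if st.prey_feedback_on_predator:
        prey_tot = sum(prey_b[p] for p in st.predation.prey) if st.predation.prey else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            percap = np.where(b_cod > COLLAPSE_FLOOR, prey_tot / np.maximum(b_cod, COLLAPSE_FLOOR), 0.0)
        feedback = np.where(
            b_cod > COLLAPSE_FLOOR,
            np.minimum(st.feedback_cap, percap / st.feedback_ref_percap),
            1.0,
        )
    else:
        feedback = 1.0

    new_adult, new_juv, catch, collapsed = {}, {}, {}, {}
    for s in STOCKS:
        p = st.stocks[s]
        g = p.growth
        if p.env_growth:
            g = g * fy.growth_mult[s]
        if p.density_dependent_growth:
            g = g * (1.0 - adult[s] / p.capacity)
        if s == "cod":
            g = g * feedback
        else:
            g = g * comp
        b_prod = np.maximum(adult[s] * (1.0 + g) + juv[s], 0.0)

        rec = _recruit(p.recruitment, adult[s])
        if p.env_recruit:
            rec = rec * fy.recruit_mult[s]
        m_juv = p.m1_juv + (m2.get("juv_cod", 0.0) if s == "cod" else 0.0)
        new_juv[s] = rec * np.exp(-m_juv)

        m_ad = p.m1_adult + (m2.get(s, 0.0) if s != "cod" else 0.0) + seal_rate[s]
        f = f_arrays[s]
        if st.f_convention == "harvest_rate":
            c = np.minimum(f * adult[s], b_prod)
            b_next = (b_prod - c) * np.exp(-m_ad)
        else:
            z = f + m_ad
            zsafe = np.where(z > 0, z, 1.0)
            c = np.where(z > 0, f / zsafe * (1.0 - np.exp(-zsafe)) * b_prod, 0.0)
            b_next = b_prod * np.exp(-z)
        collapsed[s] = b_next < COLLAPSE_FLOOR
        new_adult[s] = np.where(collapsed[s], 0.0, b_next)
        catch[s] = c
    diag = {"catch": catch, "m2": m2, "seal_rate": seal_rate, "collapsed": collapsed}
    return new_adult, new_juv, diag


# ---------------------------------------------------------------------------
# public stepping / simulation API
# ---------------------------------------------------------------------------

def step(
    state: StockState,
    f_regime: Mapping[str, float],
    forcing_year: ForcingYear,
    structure: ModelStructure,
) -> tuple[StockState, StepRecord]:
    """Advance one year for a single fishing regime."""
    forcing_year.validate()
    f_arrays = {s: np.asarray([float(f_regime[s])]) for s in STOCKS}
    _validate_f(f_arrays, structure)
    adult = {s: np.asarray([state.adult[s]], dtype=float) for s in STOCKS}
    juv = {s: np.asarray([state.juvenile[s]], dtype=float) for s in STOCKS}
    new_adult, new_juv, diag = _advance(adult, juv, f_arrays, forcing_year, structure)
    next_state = StockState(
        adult={s: float(new_adult[s][0]) for s in STOCKS},
        juvenile={s: float(new_juv[s][0]) for s in STOCKS},
    )
    record = StepRecord(
        year=forcing_year.year,
        ssb={s: state.adult[s] for s in STOCKS},
        catch={s: float(diag["catch"][s][0]) for s in STOCKS},
        m2={p: float(np.asarray(v).ravel()[0]) for p, v in diag["m2"].items()},
        seal_rate={s: float(np.asarray(diag["seal_rate"][s]).ravel()[0]) for s in STOCKS},
        collapsed={s: bool(diag["collapsed"][s][0]) for s in STOCKS},
    )
    return next_state, record


@dataclass(frozen=True)
class GridSim:
    """Yearly outputs of one model variant over a whole grid of F regimes.

    Arrays are year-by-regime (shape ``(T, n)``); ``f`` is the regime matrix
    with one column per stock in cod, herring, sprat order.  ``ssb`` holds
    beginning-of-year spawning (adult) biomass; ``catch`` the catch taken
    during that year.
    """

    years: np.ndarray
    f: np.ndarray  # (n, 3)
    ssb: Mapping[str, np.ndarray]
    juvenile: Mapping[str, np.ndarray]
    catch: Mapping[str, np.ndarray]
    m2: Mapping[str, np.ndarray]
    seal_rate: Mapping[str, np.ndarray]
    collapsed: Mapping[str, np.ndarray]

    @property
    def n_regimes(self) -> int:
        return self.f.shape[0]

    def biomass(self, stock: str) -> np.ndarray:
        """Total (adult + juvenile) biomass, year by regime."""
        return self.ssb[stock] + self.juvenile[stock]

    def extract(self, index: int) -> "SimulationResult":
        """The single-regime result at grid position ``index``."""
        sel = lambda m: {k: v[:, index].copy() for k, v in m.items()}
        return SimulationResult(
            years=self.years.copy(),
            f={s: float(self.f[index, i]) for i, s in enumerate(STOCKS)},
            ssb=sel(self.ssb),
            juvenile=sel(self.juvenile),
            catch=sel(self.catch),
            m2=sel(self.m2),
            seal_rate=sel(self.seal_rate),
            collapsed=sel(self.collapsed),
        )


@dataclass(frozen=True)
class SimulationResult:
    """Yearly SSB, catch, mortality rates and collapse flags for one run."""

    years: np.ndarray
    f: Mapping[str, float]
    ssb: Mapping[str, np.ndarray]
    juvenile: Mapping[str, np.ndarray]
    catch: Mapping[str, np.ndarray]
    m2: Mapping[str, np.ndarray]
    seal_rate: Mapping[str, np.ndarray]
    collapsed: Mapping[str, np.ndarray]

    def biomass(self, stock: str) -> np.ndarray:
        return self.ssb[stock] + self.juvenile[stock]

    def to_frame(self) -> pd.DataFrame:
        """Tidy year-by-stock table of SSB, catch and mortality rates."""
        rows = []
        for i, year in enumerate(self.years):
            for s in STOCKS:
                rows.append(
                    {
                        "year": int(year),
                        "stock": s,
                        "ssb": self.ssb[s][i],
                        "juvenile": self.juvenile[s][i],
                        "catch": self.catch[s][i],
                        "m2": self.m2.get(s, np.zeros_like(self.years, dtype=float))[i]
                        if s in self.m2
                        else 0.0,
                        "seal_rate": self.seal_rate[s][i],
                        "collapsed": bool(self.collapsed[s][i]),
                    }
                )
        return pd.DataFrame(rows)


def simulate_grid(
    structure: ModelStructure,
    f_matrix: np.ndarray,
    forcing: ForcingScenario,
    baseline: BaselineState,
) -> GridSim:
    """Simulate every fishing regime in ``f_matrix`` (n x 3, cod/herring/sprat).

    Deterministic given its inputs.  Regimes whose cod dynamics do not
    depend on clupeid state (no feedback, no cannibalism, no competition)
    produce bitwise-identical cod trajectories across clupeid-F columns.
    """
    f_matrix = np.atleast_2d(np.asarray(f_matrix, dtype=float))
    if f_matrix.shape[1] != len(STOCKS):
        raise RegimeError(f"F matrix must have {len(STOCKS)} columns")
    f_arrays = {s: np.ascontiguousarray(f_matrix[:, i]) for i, s in enumerate(STOCKS)}
    _validate_f(f_arrays, structure)
    n = f_matrix.shape[0]
    years = np.asarray(forcing.years, dtype=int)
    T = len(years)

    adult = {s: np.full(n, float(baseline.adult[s])) for s in STOCKS}
    juv = {s: np.full(n, float(baseline.juvenile[s])) for s in STOCKS}

    ssb_out = {s: np.empty((T, n)) for s in STOCKS}
    juv_out = {s: np.empty((T, n)) for s in STOCKS}
    catch_out = {s: np.empty((T, n)) for s in STOCKS}
    m2_out = {p: np.zeros((T, n)) for p in structure.predation.prey}
    seal_out = {s: np.zeros((T, n)) for s in STOCKS}
    coll_out = {s: np.zeros((T, n), dtype=bool) for s in STOCKS}

    for t, year in enumerate(years):
        fy = ForcingYear.from_scenario(forcing, year)
        fy.validate()
        for s in STOCKS:
            ssb_out[s][t] = adult[s]
            juv_out[s][t] = juv[s]
        adult, juv, diag = _advance(adult, juv, f_arrays, fy, structure)
        for s in STOCKS:
            catch_out[s][t] = diag["catch"][s]
            seal_out[s][t] = np.broadcast_to(diag["seal_rate"][s], (n,))
            coll_out[s][t] = diag["collapsed"][s]
        for p in structure.predation.prey:
            m2_out[p][t] = np.broadcast_to(diag["m2"][p], (n,))

    return GridSim(
        years=years,
        f=f_matrix,
        ssb=ssb_out,
        juvenile=juv_out,
        catch=catch_out,
        m2=m2_out,
        seal_rate=seal_out,
        collapsed=coll_out,
    )


def simulate(
    structure: ModelStructure,
    f_regime: Mapping[str, float],
    forcing: ForcingScenario,
    baseline: BaselineState,
) -> SimulationResult:
    """Simulate a single constant-F regime over the forcing scenario's years."""
    f_row = np.asarray([[float(f_regime[s]) for s in STOCKS]])
    return simulate_grid(structure, f_row, forcing, baseline).extract(0)
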
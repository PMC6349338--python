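"""End-to-end orchestration and figure-style tabular outputs.

:func:`run_full_analysis` chains the whole pipeline -- forcing generation,
ensemble simulation over the F grid, scenario selection, performance
indicators and agreement statistics -- and writes every product as plain
tab-separated tables plus a JSON run manifest:

* ``fyield_<variant>.tsv`` -- F-vs-cumulative-yield envelopes per stock and
  environmental scenario (the effect of varying the other stocks' Fs).
* ``selected_f.tsv`` / ``advice_directions.tsv`` -- optimal Fs per scenario
  and their direction relative to the Status Quo reference.
* ``indicators.tsv`` -- yearly relative changes of SSB and profits.
* ``agreement.tsv`` / ``agreement_summary.tsv`` -- per-item and averaged
  A-index and inverse-CV agreement per management scenario.

Given the same configuration and seed the result tables are byte-identical
between runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import a_index, aggregate_agreement, build_tally, categorize, inverse_cv
from .config import AnalysisConfig
from .dynamics import SimulationResult, simulate
from .errors import DataError
from .forcing import (
    BaselineState,
    ForcingScenario,
    STOCKS,
    gen_baseline,
    make_forcing,
)
from .scenarios import (
    GridEvaluation,
    INDICATORS,
    IndicatorSeries,
    ScenarioDefinition,
    SCENARIOS,
    Selection,
    build_f_grid,
    clip_regimes,
    evaluate_grid,
    performance_indicators,
    profit_frame,
    select_optimal,
)
from .structures import ModelStructure, default_ensemble

__all__ = [
    "ENV_COMBINATIONS",
    "RunManifest",
    "RunResult",
    "fyield_table",
    "advice_direction_map",
    "indicator_dependencies",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

NUTRIENTS = ("BAU", "BSAP")
SEALS = ("LSE", "HSE")
#: The 2 nutrient x 2 seal environmental futures of the factorial design.
ENV_COMBINATIONS = tuple((n, s) for n in NUTRIENTS for s in SEALS)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunManifest:
    """Traceability record written next to every set of output tables."""

    seed: int
    config: dict
    variants: tuple[str, ...]
    scenarios: tuple[str, ...]
    software_version: str
    timestamp: str

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)
            fh.write("\n")


def indicator_dependencies(missing_f: frozenset[str]) -> frozenset[str]:
    """Indicators that cannot be evaluated when some selected Fs are unknown.

    An unknown clupeid F leaves the clupeid SSBs, the pelagic-trawl profit
    and the total profit unconstrained; an unknown cod F leaves cod SSB,
    the bottom-trawl profit and the total profit unconstrained.
    """
    out: set[str] = set()
    if missing_f & {"herring", "sprat"}:
        out |= {"ssb_herring", "ssb_sprat", "profit_pt", "profit_total"}
    if "cod" in missing_f:
        out |= {"ssb_cod", "profit_bt", "profit_total"}
    return frozenset(out)


def fyield_table(
    evals_by_env: Mapping[str, GridEvaluation], stock: str
) -> pd.DataFrame:
    """Envelope of cumulative yield vs. the focal stock's F.

    For every focal-stock F value the envelope is the (min, max) cumulative
    yield across all other-stock F combinations, one row per environmental
    scenario.  All grids must be identical across environments.
    """
    first = None
    rows = []
    col = STOCKS.index(stock)
    for env, ge in evals_by_env.items():
        if first is None:
            first = ge.f
        elif ge.f.shape != first.shape or not np.array_equal(ge.f, first):
            raise DataError("incomplete or mismatched grid across environmental scenarios")
        yields = ge.cumulative_yields(stock)
        for f_val in np.unique(ge.f[:, col]):
            sel = ge.f[:, col] == f_val
            rows.append(
                {
                    "stock": stock,
                    "f": float(f_val),
                    "env": env,
                    "yield_min": float(yields[sel].min()),
                    "yield_max": float(yields[sel].max()),
                }
            )
    return pd.DataFrame(rows)


def advice_direction_map(
    selections: pd.DataFrame, reference_F: Mapping[str, float]
) -> pd.DataFrame:
    """Direction categories of selected Fs relative to the reference Fs.

    Expects the tidy ``selected_f`` table (scenario, variant, nutrient,
    seal, stock, f, status) and appends the relative change and its
    category; "no information" propagates as category 6.  A zero reference
    with a non-zero selection is flagged as a >20 % increase with a note.
    """
    rows = []
    for rec in selections.to_dict("records"):
        stock = rec["stock"]
        ref = float(reference_F[stock])
        note = ""
        if rec["status"] != "ok" or pd.isna(rec["f"]):
            rel, cat = None, categorize(None)
        elif ref == 0.0:
            if rec["f"] == 0.0:
                rel, cat = 0.0, categorize(0.0)
            else:
                rel, cat = None, 5
                note = "reference F is zero; any selection is a large increase"
        else:
            rel = (float(rec["f"]) - ref) / ref
            cat = categorize(rel)
        rows.append({**rec, "rel_change": rel, "category": cat, "note": note})
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    """In-memory view of everything a full analysis produced."""

    manifest: RunManifest
    baseline: BaselineState
    forcings: dict[tuple[str, str], ForcingScenario]
    evaluations: dict[tuple[str, str, str], GridEvaluation]  # (variant, nutrient, seal)
    selections: dict[tuple[str, str, str, str], Selection]  # (scenario, variant, nutrient, seal)
    indicators: dict[tuple[str, str, str, str], IndicatorSeries]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def has_infeasible(self) -> bool:
        return any(not s.feasible for s in self.selections.values())


def _selection_rows(result: RunResult) -> pd.DataFrame:
    rows = []
    for (scen, variant, nut, seal), sel in result.selections.items():
        for stock in STOCKS:
            f = sel.f[stock]
            if not sel.feasible:
                status = "infeasible"
            elif f is None:
                status = "no_information"
            else:
                status = "ok"
            rows.append(
                {
                    "scenario": scen,
                    "variant": variant,
                    "nutrient": nut,
                    "seal": seal,
                    "stock": stock,
                    "f": np.nan if f is None else f,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


def _indicator_rows(result: RunResult) -> pd.DataFrame:
    rows = []
    for (scen, variant, nut, seal), ind in result.indicators.items():
        for ind_name in INDICATORS:
            vals = ind.values_for(ind_name)
            for year, v in zip(ind.frame.index, vals):
                rows.append(
                    {
                        "scenario": scen,
                        "variant": variant,
                        "nutrient": nut,
                        "seal": seal,
                        "indicator": ind_name,
                        "year": int(year),
                        "rel_change": np.nan if v is None else v,
                    }
                )
    return pd.DataFrame(rows)


def _agreement_tables(
    result: RunResult,
    scenarios: Sequence[str],
    variants: Sequence[str],
    reference_F: Mapping[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item and scenario-mean agreement (A index and inverse CV)."""
    per_item_rows = []
    summary_rows = []
    for scen in scenarios:
        # --- F advice (not defined for SQ: Fs are set, not estimated) ---
        if scen != "SQ":
            a_items: dict[str, Optional[float]] = {}
            cv_items: dict[str, Optional[float]] = {}
            for stock in STOCKS:
                rels, numeric = [], []
                for variant in variants:
                    for nut, seal in ENV_COMBINATIONS:
                        sel = result.selections[(scen, variant, nut, seal)]
                        f = sel.f[stock] if sel.feasible else None
                        if f is None:
                            rels.append(None)
                            numeric.append(None)
                        else:
                            ref = float(reference_F[stock])
                            rels.append((f - ref) / ref if ref else None)
                            numeric.append(f)
                tally = build_tally(rels, target="f_advice")
                a_items[stock] = a_index(tally)
                cv_items[stock] = inverse_cv(numeric)
                per_item_rows.append(
                    dict(scenario=scen, target="f_advice", measure="A", item=stock,
                         value=a_items[stock], n=tally.n)
                )
                per_item_rows.append(
                    dict(scenario=scen, target="f_advice", measure="inv_cv", item=stock,
                         value=cv_items[stock], n=sum(v is not None for v in numeric))
                )
            summary_rows.append(
                dict(scenario=scen, target="f_advice", measure="A",
                     value=aggregate_agreement(a_items))
            )
            if any(v is not None for v in cv_items.values()):
                summary_rows.append(
                    dict(scenario=scen, target="f_advice", measure="inv_cv",
                         value=aggregate_agreement(cv_items))
                )
        # --- performance indicators ---
        a_items = {}
        cv_items = {}
        for ind_name in INDICATORS:
            cases = []
            pooled: list[Optional[float]] = []
            for variant in variants:
                for nut, seal in ENV_COMBINATIONS:
                    series = result.indicators[(scen, variant, nut, seal)]
                    vals = series.values_for(ind_name)
                    cases.append(vals)
                    pooled.extend(vals)
            tally = build_tally(cases, target="indicator")
            a_items[ind_name] = a_index(tally)
            cv_items[ind_name] = inverse_cv(pooled)
            per_item_rows.append(
                dict(scenario=scen, target="indicator", measure="A", item=ind_name,
                     value=a_items[ind_name], n=tally.n)
            )
            per_item_rows.append(
                dict(scenario=scen, target="indicator", measure="inv_cv", item=ind_name,
                     value=cv_items[ind_name],
                     n=sum(v is not None for v in pooled))
            )
        summary_rows.append(
            dict(scenario=scen, target="indicator", measure="A",
                 value=aggregate_agreement(a_items))
        )
        if any(v is not None for v in cv_items.values()):
            summary_rows.append(
                dict(scenario=scen, target="indicator", measure="inv_cv",
                     value=aggregate_agreement(cv_items))
            )
    return pd.DataFrame(per_item_rows), pd.DataFrame(summary_rows)


def _indicator_series_for(
    ge: GridEvaluation,
    sel: Selection,
    baseline: BaselineState,
) -> IndicatorSeries:
    """Indicators at the selected regime; unknown Fs are filled with the
    reference value for simulation and their dependent indicators masked."""
    eval_years = np.arange(2020, 2033)
    eval_years = eval_years[np.isin(eval_years, ge.sim.years)]
    if not sel.feasible:
        frame = pd.DataFrame(
            {ind: np.full(len(eval_years), np.nan) for ind in INDICATORS},
            index=pd.Index(eval_years, name="year"),
        )
        return IndicatorSeries(frame=frame, no_information=frozenset(INDICATORS))
    if sel.index is not None and not sel.no_information:
        run = ge.sim.extract(sel.index)
        profits = ge.extract_profit_frame(sel.index)
    else:
        f_full = {
            s: (sel.f[s] if sel.f[s] is not None else float(baseline.reference_F[s]))
            for s in STOCKS
        }
        run = simulate(ge.structure, f_full, ge.forcing, baseline)
        profits = profit_frame(run, ge.forcing.seal_biomass, ge.econ)
    series = performance_indicators(
        run, profits, baseline.reference_indicator_means, years=eval_years
    )
    masked = series.no_information | indicator_dependencies(sel.no_information)
    return IndicatorSeries(frame=series.frame, no_information=frozenset(masked))


def run_full_analysis(
    config: AnalysisConfig | None,
    seed: int,
    out_dir,
    write: bool = True,
) -> RunResult:
    """Execute the whole pipeline and (optionally) write all result tables.

    Deterministic given ``(config, seed)``: repeated runs produce
    byte-identical tables.  Progress is logged at stage granularity.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir) if out_dir is not None else None
    if write:
        if out is None:
            raise DataError("an output directory is required when writing tables")
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    logger.info("stage 1/5: generating forcing scenarios")
    years = config.years
    forcings = {
        (n, s): make_forcing(
            n, s, seed, years=years, seal_b0=config.seal_b0,
            noise_sd=config.noise_sd, ar_coeff=config.ar_coeff,
        )
        for n, s in ENV_COMBINATIONS
    }
    baseline = gen_baseline(seed, config.economics)

    logger.info("stage 2/5: ensemble simulation over the F grid")
    ensemble = {m.name: m for m in default_ensemble() if m.name in config.variants}
    base_regimes = build_f_grid(config.f_ranges, config.f_step)
    evaluations: dict[tuple[str, str, str], GridEvaluation] = {}
    for name, structure in ensemble.items():
        regimes = clip_regimes(base_regimes, structure)
        for (n, s), forcing in forcings.items():
            evaluations[(name, n, s)] = evaluate_grid(
                structure, regimes, forcing, baseline, config.economics
            )

    logger.info("stage 3/5: scenario selection")
    scenario_defs = {
        name: (
            SCENARIOS[name]
            if name != "PR"
            else ScenarioDefinition("PR", SCENARIOS["PR"].description, blim=dict(config.blim))
        )
        for name in config.scenarios
    }
    selections: dict[tuple[str, str, str, str], Selection] = {}
    for scen, sdef in scenario_defs.items():
        for name in ensemble:
            for n, s in ENV_COMBINATIONS:
                selections[(scen, name, n, s)] = select_optimal(
                    evaluations[(name, n, s)], sdef, config.insensitivity_tol
                )

    logger.info("stage 4/5: performance indicators")
    indicators = {
        key: _indicator_series_for(evaluations[key[1:]], sel, baseline)
        for key, sel in selections.items()
    }

    logger.info("stage 5/5: agreement statistics and tables")
    manifest = RunManifest(
        seed=int(seed),
        config=config.to_dict(),
        variants=tuple(ensemble),
        scenarios=tuple(scenario_defs),
        software_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    result = RunResult(
        manifest=manifest,
        baseline=baseline,
        forcings=forcings,
        evaluations=evaluations,
        selections=selections,
        indicators=indicators,
    )

    sel_table = _selection_rows(result)
    result.tables["selected_f"] = sel_table
    result.tables["advice_directions"] = advice_direction_map(
        sel_table, baseline.reference_F
    )
    result.tables["indicators"] = _indicator_rows(result)
    per_item, summary = _agreement_tables(
        result, list(scenario_defs), list(ensemble), baseline.reference_F
    )
    result.tables["agreement"] = per_item
    result.tables["agreement_summary"] = summary
    for name in ensemble:
        evs = {f"{n}-{s}": evaluations[(name, n, s)] for n, s in ENV_COMBINATIONS}
        result.tables[f"fyield_{name}"] = pd.concat(
            [fyield_table(evs, stock) for stock in STOCKS], ignore_index=True
        )

    if write:
        for key, frame in result.tables.items():
            frame.to_csv(out / f"{key}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        for (n, s), forcing in forcings.items():
            forcing.write_tsv(out / f"forcing_{n}_{s}.tsv")
        manifest.write(out / "manifest.json")
    logger.info("analysis finished in %.1f s", time.time() - t0)
    return result
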
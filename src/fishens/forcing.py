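"""Synthetic environmental forcing and baseline states.

The projection experiments need three external inputs: (i) nutrient-driven
multipliers on growth efficiency and recruitment under two nutrient-load
futures (BAU, business-as-usual, with continued eutrophication; BSAP, the
Baltic Sea Action Plan load reductions), (ii) a grey-seal biomass
trajectory growing at 5 %/yr (LSE) or 10 %/yr (HSE), and (iii) a baseline
stock state with the 2011-2013 reference fishing mortalities.  In the
original study these came from a coupled hydro-biogeochemical hindcast,
seal surveys and stock assessments; here they are generated synthetically
so that the whole pipeline is reproducible from a seed.

The multiplier generator is a label-specific linear trend times
log-AR(1) noise, so every multiplier is strictly positive for every seed.
The BSAP trend gives cod better growth conditions than BAU (load
reductions relieve deep-water oxygen stress on cod reproduction volume),
while BAU mildly favours sprat via higher planktonic production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .economics import DEFAULT_ECONOMICS, EconomicParams, yearly_profit
from .errors import ConfigurationError, DomainError, ForcingError

__all__ = [
    "STOCKS",
    "DEFAULT_YEARS",
    "SEAL_GROWTH_RATES",
    "ForcingScenario",
    "BaselineState",
    "gen_seal_trajectory",
    "gen_environment_series",
    "gen_baseline",
    "make_forcing",
]

STOCKS = ("cod", "herring", "sprat")
NUTRIENT_LABELS = ("BAU", "BSAP")
SEAL_GROWTH_RATES = {"LSE": 0.05, "HSE": 0.10}

#: Projection window, inclusive (19 years).
DEFAULT_YEARS = np.arange(2014, 2033)

# Linear trend endpoints (value in first year -> value in last year) for the
# growth-efficiency and recruitment multipliers under each nutrient label.
# Chosen so BSAP >= BAU for cod in every year while BAU mildly favours sprat.
_GROWTH_TRENDS = {
    "BAU": {"cod": (1.00, 0.90), "herring": (1.00, 0.95), "sprat": (1.00, 1.05)},
    "BSAP": {"cod": (1.00, 1.10), "herring": (1.00, 1.05), "sprat": (1.00, 0.97)},
}
_RECRUIT_TRENDS = {
    "BAU": {"cod": (1.00, 0.92), "herring": (1.00, 0.97), "sprat": (1.00, 1.08)},
    "BSAP": {"cod": (1.00, 1.08), "herring": (1.00, 1.03), "sprat": (1.00, 0.95)},
}


def gen_seal_trajectory(b0: float, growth_rate: float, years) -> np.ndarray:
    """Deterministic exponential seal-biomass series.

    ``series[t] = b0 * (1 + growth_rate)**(t - t0)`` for each year ``t`` in
    ``years`` (first year ``t0`` undiscounted growth).  Relative units.
    """
    if b0 <= 0:
        raise DomainError(f"initial seal biomass must be > 0, got {b0}")
    if growth_rate < 0:
        raise DomainError("seal growth rate must be >= 0")
    years = np.asarray(years, dtype=int)
    return b0 * (1.0 + growth_rate) ** (years - years[0]).astype(float)


def _trend(endpoints: tuple[float, float], n: int) -> np.ndarray:
    return np.linspace(endpoints[0], endpoints[1], n)


def gen_environment_series(
    nutrient_label: str,
    years,
    seed: int,
    noise_sd: float = 0.05,
    ar_coeff: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Growth-efficiency and recruitment multiplier series for one nutrient label.

    Returns two year-by-stock DataFrames.  Each series is a deterministic
    label-specific linear trend multiplied by ``exp`` of a stationary AR(1)
    process (autocorrelation ``ar_coeff``, marginal s.d. ``noise_sd``), so
    positivity holds for every seed and ``noise_sd = 0`` recovers the trend
    exactly.  Identical ``(label, years, seed)`` give identical tables.
    """
    if nutrient_label not in NUTRIENT_LABELS:
        raise ConfigurationError(
            f"unknown nutrient label {nutrient_label!r}; expected one of {NUTRIENT_LABELS}"
        )
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if not 0 <= ar_coeff < 1:
        raise DomainError("ar_coeff must be in [0, 1)")
    years = np.asarray(years, dtype=int)
    n = len(years)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), NUTRIENT_LABELS.index(nutrient_label)])
    )
    out = {}
    for kind, trends in (("growth", _GROWTH_TRENDS), ("recruit", _RECRUIT_TRENDS)):
        cols = {}
        for stock in STOCKS:
            z = rng.standard_normal(n)
            e = np.empty(n)
            e[0] = noise_sd * z[0]
            innov_sd = noise_sd * np.sqrt(1.0 - ar_coeff**2)
            for t in range(1, n):
                e[t] = ar_coeff * e[t - 1] + innov_sd * z[t]
            cols[stock] = _trend(trends[nutrient_label][stock], n) * np.exp(e)
        out[kind] = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return out["growth"], out["recruit"]


@dataclass(frozen=True)
class ForcingScenario:
    """One environmental future: nutrient multipliers plus a seal trajectory."""

    nutrient_label: str
    seal_label: str
    years: np.ndarray
    growth_multiplier: pd.DataFrame  # year x stock
    recruit_multiplier: pd.DataFrame  # year x stock
    seal_biomass: pd.Series  # year-indexed

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "years", years)
        for name, df in (
            ("growth_multiplier", self.growth_multiplier),
            ("recruit_multiplier", self.recruit_multiplier),
        ):
            if list(df.index) != list(years):
                raise ForcingError(f"{name} does not cover every year of the scenario")
            if not np.all(np.isfinite(df.to_numpy())) or np.any(df.to_numpy() <= 0):
                raise ForcingError(f"{name} must be finite and strictly positive")
        if list(self.seal_biomass.index) != list(years):
            raise ForcingError("seal series does not cover every year of the scenario")
        if np.any(self.seal_biomass.to_numpy() <= 0):
            raise ForcingError("seal biomass must be strictly positive")

    @property
    def label(self) -> str:
        return f"{self.nutrient_label}-{self.seal_label}"

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: year, stock, growth_multiplier, recruit_multiplier, seal_biomass."""
        rows = []
        for year in self.years:
            for stock in STOCKS:
                rows.append(
                    {
                        "year": int(year),
                        "stock": stock,
                        "growth_multiplier": self.growth_multiplier.loc[year, stock],
                        "recruit_multiplier": self.recruit_multiplier.loc[year, stock],
                        "seal_biomass": self.seal_biomass.loc[year],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, nutrient_label: str, seal_label: str
    ) -> "ForcingScenario":
        years = np.sort(frame["year"].unique())
        growth = frame.pivot(index="year", columns="stock", values="growth_multiplier")[list(STOCKS)]
        recruit = frame.pivot(index="year", columns="stock", values="recruit_multiplier")[list(STOCKS)]
        seal = frame.drop_duplicates("year").set_index("year")["seal_biomass"]
        return cls(nutrient_label, seal_label, years, growth, recruit, seal.loc[years])

    @classmethod
    def read_tsv(cls, path, nutrient_label: str, seal_label: str) -> "ForcingScenario":
        return cls.from_frame(pd.read_csv(path, sep="\t"), nutrient_label, seal_label)


def make_forcing(
    nutrient_label: str,
    seal_label: str,
    seed: int,
    years=None,
    seal_b0: float = 1.0,
    noise_sd: float = 0.05,
    ar_coeff: float = 0.6,
) -> ForcingScenario:
    """Assemble a full :class:`ForcingScenario` for one nutrient x seal combination.

    The nutrient multipliers depend only on ``(nutrient_label, seed)``, so the
    two seal variants of a nutrient scenario share identical multiplier
    tables, as they would if both were driven by the same biogeochemical run.
    """
    if seal_label not in SEAL_GROWTH_RATES:
        raise ConfigurationError(
            f"unknown seal label {seal_label!r}; expected one of {tuple(SEAL_GROWTH_RATES)}"
        )
    years = DEFAULT_YEARS if years is None else np.asarray(years, dtype=int)
    growth, recruit = gen_environment_series(
        nutrient_label, years, seed, noise_sd=noise_sd, ar_coeff=ar_coeff
    )
    seal = pd.Series(
        gen_seal_trajectory(seal_b0, SEAL_GROWTH_RATES[seal_label], years),
        index=pd.Index(years, name="year"),
    )
    return ForcingScenario(nutrient_label, seal_label, years, growth, recruit, seal)


# Baltic-like relative biomasses, roughly in units of 100 kt.
_BASE_ADULT = {"cod": 1.0, "herring": 7.0, "sprat": 8.0}
_BASE_JUV = {"cod": 0.6, "herring": 2.6, "sprat": 4.4}
#: 2011-2013 mean fishing mortalities used by the Status Quo scenario.
_REFERENCE_F = {"cod": 0.5, "herring": 0.25, "sprat": 0.3}


@dataclass(frozen=True)
class BaselineState:
    """Initial stock state, reference Fs and 2011-2013 reference indicator means."""

    adult: Mapping[str, float]
    juvenile: Mapping[str, float]
    reference_F: Mapping[str, float]
    reference_indicator_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in STOCKS:
            if self.adult[s] <= 0 or self.juvenile[s] <= 0:
                raise DomainError(f"baseline biomass for {s} must be > 0")
            if self.reference_F[s] < 0:
                raise DomainError(f"reference F for {s} must be >= 0")


def gen_baseline(
    seed: int, econ: EconomicParams = DEFAULT_ECONOMICS, jitter_sd: float = 0.03
) -> BaselineState:
    """Baseline state with seeded log-normal jitter on the stock biomasses.

    Reference indicator means are derived from the jittered baseline: SSB
    references are the adult biomasses themselves, profit references come
    from applying the reference Fs as harvest rates to the baseline and
    pricing the resulting landings at unit seal biomass.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    adult = {s: _BASE_ADULT[s] * float(np.exp(jitter_sd * rng.standard_normal())) for s in STOCKS}
    juv = {s: _BASE_JUV[s] * float(np.exp(jitter_sd * rng.standard_normal())) for s in STOCKS}
    ref_f = dict(_REFERENCE_F)
    landings = {s: ref_f[s] * adult[s] for s in STOCKS}
    rec = yearly_profit(landings, ref_f["cod"], seal_biomass=1.0, params=econ)
    means = {
        "ssb_cod": adult["cod"],
        "ssb_herring": adult["herring"],
        "ssb_sprat": adult["sprat"],
        "profit_bt": rec.profit_bt,
        "profit_pt": rec.profit_pt,
        "profit_total": rec.profit_total,
    }
    return BaselineState(adult=adult, juvenile=juv, reference_F=ref_f, reference_indicator_means=means)
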
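import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fishens", deadline=None, derandomize=True)
settings.load_profile("fishens")

from fishens.economics import EconomicParams
from fishens.forcing import (
    BaselineState,
    ForcingScenario,
    STOCKS,
    gen_baseline,
    make_forcing,
)
from fishens.structures import default_ensemble


@pytest.fixture(scope="session")
def baseline() -> BaselineState:
    return gen_baseline(seed=1)


@pytest.fixture(scope="session")
def forcing() -> ForcingScenario:
    """Default BAU / low-seal-growth forcing with noise, seed 1."""
    return make_forcing("BAU", "LSE", seed=1)


@pytest.fixture(scope="session")
def forcing_quiet() -> ForcingScenario:
    """Noise-free BAU / LSE forcing: multipliers equal their trends."""
    return make_forcing("BAU", "LSE", seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def ensemble() -> dict:
    return {m.name: m for m in default_ensemble()}


def flat_forcing(n_years: int = 200, first_year: int = 2014) -> ForcingScenario:
    """Constant unit forcing over a long horizon, for equilibrium studies."""
    years = np.arange(first_year, first_year + n_years)
    idx = pd.Index(years, name="year")
    ones = pd.DataFrame({s: np.ones(n_years) for s in STOCKS}, index=idx)
    return ForcingScenario(
        "BAU", "LSE", years, ones, ones.copy(), pd.Series(np.ones(n_years), index=idx)
    )


def inert_baseline(cod_adult: float, ref_f_cod: float = 0.5) -> BaselineState:
    """Baseline with the clupeid pools effectively empty (single-stock runs)."""
    tiny = 1e-12
    return BaselineState(
        adult={"cod": cod_adult, "herring": tiny, "sprat": tiny},
        juvenile={s: tiny for s in STOCKS},
        reference_F={"cod": ref_f_cod, "herring": 0.0, "sprat": 0.0},
    )


@pytest.fixture(scope="session")
def yield_economics() -> EconomicParams:
    """Degenerate economics where the PE objective equals undiscounted cod yield."""
    return EconomicParams(
        price={"cod": 1.0, "herring": 0.0, "sprat": 0.0},
        cod_cost_coeff={"BT": 0.0, "GN": 0.0},
        clupeid_cost_coeff=0.0,
        cod_fleet_split=1.0,
        discount_rate=0.0,
        seal_damage_enabled=False,
    )
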
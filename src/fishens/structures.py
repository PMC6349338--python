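"""Structural definitions of the ensemble members.

Each ensemble member is a multispecies biomass-dynamics model for cod,
herring and sprat assembled from a fixed set of switchable assumptions:
stock-recruitment form, cod predation form, prey-to-predator feedback,
clupeid competition, seal predation form, environmental coupling, density
dependence of growth, and the fishing-mortality convention.  The three
canonical members shipped by :func:`default_ensemble` differ along exactly
those axes, mirroring the contrast between a whole-food-web simulator
("ewe_like"), an age-structured statistical model ("gadget_like") and a
minimal multispecies production model ("mspm_like").

All biomasses are in relative units (roughly 100 kt); rates are per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigurationError
from .forcing import STOCKS

__all__ = [
    "PREY",
    "Recruitment",
    "StockParams",
    "Predation",
    "SealPredation",
    "ModelStructure",
    "default_ensemble",
    "single_stock_logistic",
]

#: Prey items available to adult cod. "juv_cod" is the juvenile cod pool
#: (cannibalism); predation on herring and sprat acts on their adult pool.
PREY = ("herring", "sprat", "juv_cod")

RECRUITMENT_FORMS = ("ricker", "beverton_holt", "hockey_stick", "none")
PREDATION_FORMS = ("none", "linear_pred_declining_prey", "saturating_pred")
SEAL_FORMS = ("none", "linear", "saturating")
F_CONVENTIONS = ("harvest_rate", "instantaneous")


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ConfigurationError(f"{name} must be finite and >= 0, got {value}")


@dataclass(frozen=True)
class Recruitment:
    """Stock-recruitment relationship of one stock.

    ``ricker``: a*S*exp(-b*S); ``beverton_holt``: a*S/(b+S);
    ``hockey_stick``: a*min(S, s_break)/s_break; ``none``: no recruitment
    (used by reduced single-stock variants where density-dependent adult
    growth closes the life cycle on its own).
    """

    form: str
    a: float = 0.0
    b: float = 1.0
    s_break: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in RECRUITMENT_FORMS:
            raise ConfigurationError(f"unknown recruitment form {self.form!r}")
        if self.form != "none":
            if self.a <= 0:
                raise ConfigurationError("recruitment a must be > 0")
            if self.form in ("ricker", "beverton_holt") and self.b <= 0:
                raise ConfigurationError("recruitment b must be > 0")
            if self.form == "hockey_stick" and self.s_break <= 0:
                raise ConfigurationError("hockey-stick s_break must be > 0")


@dataclass(frozen=True)
class StockParams:
    """Per-stock life-history parameters and coupling flags.

    ``growth`` is the surplus-production (growth-efficiency) coefficient of
    the adult pool; ``capacity`` the biomass at which density-dependent
    growth reaches zero (used only when ``density_dependent_growth``);
    ``m1_adult``/``m1_juv`` are residual natural mortality rates.
    """

    growth: float
    m1_adult: float
    m1_juv: float
    recruitment: Recruitment
    capacity: float = math.inf
    env_growth: bool = False
    env_recruit: bool = False
    density_dependent_growth: bool = False

    def __post_init__(self) -> None:
        _check_finite_nonneg("growth", self.growth)
        _check_finite_nonneg("m1_adult", self.m1_adult)
        _check_finite_nonneg("m1_juv", self.m1_juv)
        if self.density_dependent_growth and not (self.capacity > 0):
            raise ConfigurationError("capacity must be > 0 when growth is density dependent")


@dataclass(frozen=True)
class Predation:
    """Functional form of cod predation mortality on its prey.

    ``linear_pred_declining_prey``: M2_p = c_p * B_cod / (D + sum of prey
    biomasses), i.e. linear in predator biomass and declining in the total
    prey pool (prey share a fixed predator ration); capped at ``guard_max``,
    which is also the value returned when the denominator is zero.

    ``saturating_pred``: M2_p = m_max_p * B_cod/(K + B_cod) * B_p/(A_p + B_p),
    saturating in predator biomass (cap m_max_p) and increasing in the prey's
    own biomass (foraging-arena-like vulnerability; A_p = 0 disables it).
    """

    form: str
    prey: tuple[str, ...] = ()
    attack: Mapping[str, float] = field(default_factory=dict)
    pool_half_sat: float = 0.0  # D
    guard_max: float = 2.0
    max_rate: Mapping[str, float] = field(default_factory=dict)
    pred_half_sat: float = 1.0  # K
    avail_half_sat: Mapping[str, float] = field(default_factory=dict)  # A_p

    def __post_init__(self) -> None:
        if self.form not in PREDATION_FORMS:
            raise ConfigurationError(f"unknown predation form {self.form!r}")
        for p in self.prey:
            if p not in PREY:
                raise ConfigurationError(f"unknown prey item {p!r}")
        _check_finite_nonneg("pool_half_sat", self.pool_half_sat)
        _check_finite_nonneg("guard_max", self.guard_max)
        _check_finite_nonneg("pred_half_sat", self.pred_half_sat)
        for m in (self.attack, self.max_rate, self.avail_half_sat):
            for k, v in m.items():
                _check_finite_nonneg(f"predation parameter for {k}", v)


@dataclass(frozen=True)
class SealPredation:
    """Seal-induced mortality on fish stocks.

    ``linear``: coeff_s * B_seal * B_prey/(prey_half + B_prey) -- unbounded
    in seal biomass.  ``saturating``: coeff_s * B_seal/(seal_half + B_seal)
    * B_prey/(prey_half + B_prey) -- bounded above by coeff_s however large
    the seal population grows.
    """

    form: str = "none"
    coeff: Mapping[str, float] = field(default_factory=dict)
    seal_half_sat: float = 0.5
    prey_half_sat: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in SEAL_FORMS:
            raise ConfigurationError(f"unknown seal predation form {self.form!r}")
        for k, v in self.coeff.items():
            _check_finite_nonneg(f"seal coefficient for {k}", v)
        _check_finite_nonneg("seal_half_sat", self.seal_half_sat)


@dataclass(frozen=True)
class ModelStructure:
    """One ensemble member: per-stock parameters plus interaction switches."""

    name: str
    stocks: Mapping[str, StockParams]
    predation: Predation = field(default_factory=lambda: Predation(form="none"))
    seal: SealPredation = field(default_factory=SealPredation)
    prey_feedback_on_predator: bool = False
    feedback_ref_percap: float = 15.0
    feedback_cap: float = 1.5
    clupeid_competition: bool = False
    competition_coeff: float = 0.02
    f_convention: str = "harvest_rate"

    def __post_init__(self) -> None:
        missing = [s for s in STOCKS if s not in self.stocks]
        if missing:
            raise ConfigurationError(f"missing stock parameters for {missing}")
        if self.f_convention not in F_CONVENTIONS:
            raise ConfigurationError(f"unknown F convention {self.f_convention!r}")
        if self.prey_feedback_on_predator and self.feedback_ref_percap <= 0:
            raise ConfigurationError("feedback_ref_percap must be > 0")
        _check_finite_nonneg("competition_coeff", self.competition_coeff)

    @property
    def f_max(self) -> float:
        """Largest admissible F under this member's convention."""
        return 1.0 if self.f_convention == "harvest_rate" else math.inf

    def replace(self, **kwargs) -> "ModelStructure":
        return replace(self, **kwargs)


def _shared_stock(name: str, recruitment: Recruitment, **flags) -> StockParams:
    base = {
        "cod": dict(growth=0.10, m1_adult=0.20, m1_juv=0.30),
        "herring": dict(growth=0.10, m1_adult=0.20, m1_juv=0.30),
        "sprat": dict(growth=0.10, m1_adult=0.30, m1_juv=0.40),
    }[name]
    return StockParams(recruitment=recruitment, **base, **flags)


def default_ensemble() -> tuple[ModelStructure, ModelStructure, ModelStructure]:
    """The three canonical structural variants.

    ========================  ==============  ==============  =================
    assumption                ewe_like        gadget_like     mspm_like
    ========================  ==============  ==============  =================
    recruitment               Beverton-Holt   hockey-stick    Ricker (cod),
                              (env-forced)    (all stocks)    Beverton-Holt
    cod predation             saturating,     saturating,     linear in cod,
                              incl. juv cod   no cannibalism  declining in prey
    prey feedback on cod      growth x food   none            via cannibalism
    clupeid competition       yes             no              no
    seal predation            saturating      linear          none
    environmental forcing     all stocks      none            cod+herring growth
    density-dep. growth       no              no              sprat
    F convention              harvest rate    harvest rate    instantaneous
    ========================  ==============  ==============  =================
    """
    ewe = ModelStructure(
        name="ewe_like",
        stocks={
            "cod": _shared_stock(
                "cod",
                Recruitment("beverton_holt", a=1.26, b=0.5),
                env_growth=True,
                env_recruit=True,
            ),
            "herring": _shared_stock(
                "herring",
                Recruitment("beverton_holt", a=5.0, b=3.0),
                env_growth=True,
                env_recruit=True,
            ),
            "sprat": _shared_stock(
                "sprat",
                Recruitment("beverton_holt", a=10.0, b=4.4),
                env_growth=True,
                env_recruit=True,
            ),
        },
        predation=Predation(
            form="saturating_pred",
            prey=("herring", "sprat", "juv_cod"),
            # herring far less vulnerable to cod than sprat
            max_rate={"herring": 0.08, "sprat": 0.25, "juv_cod": 0.35},
            pred_half_sat=1.0,
            avail_half_sat={"herring": 3.0, "sprat": 3.0, "juv_cod": 0.5},
        ),
        seal=SealPredation(
            form="saturating",
            coeff={"cod": 0.06},
            seal_half_sat=0.5,
            prey_half_sat={"cod": 1.0},
        ),
        prey_feedback_on_predator=True,
        clupeid_competition=True,
        f_convention="harvest_rate",
    )
    gadget = ModelStructure(
        name="gadget_like",
        stocks={
            "cod": _shared_stock("cod", Recruitment("hockey_stick", a=0.84, s_break=0.5)),
            "herring": _shared_stock("herring", Recruitment("hockey_stick", a=3.5, s_break=2.0)),
            "sprat": _shared_stock("sprat", Recruitment("hockey_stick", a=6.6, s_break=2.5)),
        },
        predation=Predation(
            form="saturating_pred",
            prey=("herring", "sprat"),
            max_rate={"herring": 0.15, "sprat": 0.25},
            pred_half_sat=1.0,
            avail_half_sat={"herring": 3.0, "sprat": 3.0},
        ),
        seal=SealPredation(
            form="linear",
            coeff={"cod": 0.05, "herring": 0.01},
            prey_half_sat={"cod": 1.0, "herring": 7.0},
        ),
        prey_feedback_on_predator=False,
        f_convention="harvest_rate",
    )
    mspm = ModelStructure(
        name="mspm_like",
        stocks={
            "cod": _shared_stock(
                "cod", Recruitment("ricker", a=1.65, b=0.675), env_growth=True
            ),
            "herring": _shared_stock(
                "herring", Recruitment("beverton_holt", a=5.0, b=3.04), env_growth=True
            ),
            "sprat": _shared_stock(
                "sprat",
                Recruitment("beverton_holt", a=10.2, b=4.4),
                density_dependent_growth=True,
                capacity=16.0,
            ),
        },
        predation=Predation(
            form="linear_pred_declining_prey",
            prey=("herring", "sprat", "juv_cod"),
            attack={"herring": 1.0, "sprat": 2.0, "juv_cod": 3.0},
            pool_half_sat=2.0,
            guard_max=2.0,
        ),
        seal=SealPredation(form="none"),
        prey_feedback_on_predator=False,
        f_convention="instantaneous",
    )
    return ewe, gadget, mspm


def single_stock_logistic(
    r: float, K: float, f_convention: str = "harvest_rate", name: str = "logistic"
) -> ModelStructure:
    """Reduced variant whose cod pool follows pure logistic surplus production.

    Recruitment, natural mortality, predation, seals and forcing are all
    off, so the cod dynamics collapse to B' = B + r*B*(1-B/K) - C, the
    discrete Schaefer model, with herring and sprat inert.  Used for
    closed-form verification.
    """
    inert = Recruitment("none")
    off = dict(m1_adult=0.0, m1_juv=0.0)
    return ModelStructure(
        name=name,
        stocks={
            "cod": StockParams(
                growth=r,
                recruitment=inert,
                capacity=K,
                density_dependent_growth=True,
                **off,
            ),
            "herring": StockParams(growth=0.0, recruitment=inert, **off),
            "sprat": StockParams(growth=0.0, recruitment=inert, **off),
        },
        predation=Predation(form="none"),
        seal=SealPredation(form="none"),
        f_convention=f_convention,
    )
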
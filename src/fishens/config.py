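"""Run configuration: defaults, YAML round-trip and validation.

A configuration captures everything a full analysis needs besides the
seed: the projection years, the F grid, the scenario and variant lists,
the Piscivore-Recovery biomass limits, the economics block and the
synthetic-forcing settings.  Validation reports the offending field path
so config errors surface before any computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .economics import EconomicParams
from .errors import ConfigurationError
from .forcing import STOCKS
from .scenarios import DEFAULT_BLIM, DEFAULT_F_RANGE, DEFAULT_F_STEP, SCENARIOS

__all__ = ["AnalysisConfig", "load_config"]

_VARIANTS = ("ewe_like", "gadget_like", "mspm_like")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs except the seed."""

    first_year: int = 2014
    last_year: int = 2032
    f_min: float = DEFAULT_F_RANGE[0]
    f_max: float = DEFAULT_F_RANGE[1]
    f_step: float = DEFAULT_F_STEP
    scenarios: Sequence[str] = tuple(SCENARIOS)
    variants: Sequence[str] = _VARIANTS
    blim: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BLIM))
    insensitivity_tol: float = 1e-6
    noise_sd: float = 0.05
    ar_coeff: float = 0.6
    seal_b0: float = 1.0
    economics: EconomicParams = field(default_factory=EconomicParams)

    def __post_init__(self) -> None:
        errors = []
        if self.last_year < self.first_year:
            errors.append("last_year: must be >= first_year")
        if self.f_step <= 0:
            errors.append("f_step: must be > 0")
        if self.f_max < self.f_min or self.f_min < 0:
            errors.append("f_min/f_max: need 0 <= f_min <= f_max")
        for s in self.scenarios:
            if s not in SCENARIOS:
                errors.append(f"scenarios: unknown scenario {s!r}")
        for v in self.variants:
            if v not in _VARIANTS:
                errors.append(f"variants: unknown variant {v!r}")
        for s in ("herring", "sprat"):
            if s not in self.blim or self.blim[s] <= 0:
                errors.append(f"blim.{s}: must be present and > 0")
        if self.noise_sd < 0:
            errors.append("noise_sd: must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            errors.append("ar_coeff: must be in [0, 1)")
        if self.seal_b0 <= 0:
            errors.append("seal_b0: must be > 0")
        if errors:
            raise ConfigurationError("invalid configuration: " + "; ".join(errors))

    @property
    def years(self):
        import numpy as np

        return np.arange(self.first_year, self.last_year + 1)

    @property
    def f_ranges(self) -> dict[str, tuple[float, float]]:
        return {s: (self.f_min, self.f_max) for s in STOCKS}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["variants"] = list(self.variants)
        d["economics"] = {
            "price": dict(self.economics.price),
            "cod_cost_coeff": dict(self.economics.cod_cost_coeff),
            "clupeid_cost_coeff": self.economics.clupeid_cost_coeff,
            "cod_fleet_split": self.economics.cod_fleet_split,
            "discount_rate": self.economics.discount_rate,
            "seal_damage_coeff": self.economics.seal_damage_coeff,
            "seal_damage_enabled": self.economics.seal_damage_enabled,
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        data = dict(data)
        econ = data.pop("economics", None)
        kwargs = {}
        valid = {f for f in cls.__dataclass_fields__}
        for k, v in data.items():
            if k not in valid:
                raise ConfigurationError(f"{k}: unknown configuration field")
            kwargs[k] = v
        if "scenarios" in kwargs:
            kwargs["scenarios"] = tuple(kwargs["scenarios"])
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        if econ is not None:
            try:
                kwargs["economics"] = EconomicParams(**econ)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"economics: {exc}") from exc
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def load_config(path) -> AnalysisConfig:
    """Read a YAML configuration file; missing keys fall back to defaults."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigurationError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return AnalysisConfig.from_dict(data)
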
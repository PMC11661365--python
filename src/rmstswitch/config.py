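"""Scenario configuration: the full parameter set of one simulated trial.

Parameter names follow the conventions of the field's trial-design software
(dots in names such as ``s.dist`` or ``censoring.rate`` map to underscores):

n, r            control-arm size and experimental:control allocation ratio
m1, m2, shape   median survivals of the two arms and the common Weibull shape
f1 | f2, m0 | margin   the (mutually exclusive) margin options
ps, rs, rho_s, s_dist  switching probability, mean-ratio E(s)/E(T),
                correlation target, and switching-time family
censoring_rate  total control-arm censoring probability, or "AC.only" for
                administrative censoring only
Ta, Te, tau     accrual duration, trial duration, RMST horizon
one_sided_alpha significance level of the one-sided NI test
TXswitch        switching direction, "1to2" (control to experimental,
                default) or "2to1"
n_simulations, seed    Monte-Carlo controls
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .switching import SWITCH_FAMILIES

__all__ = ["ConfigError", "ScenarioConfig"]


class ConfigError(ValueError):
    """An invalid or inconsistent scenario parameter."""


_FIELD_NAMES = (
    "n", "r", "m1", "m2", "shape", "f1", "m0", "f2", "margin",
    "ps", "rs", "rho_s", "s_dist", "censoring_rate",
    "Ta", "Te", "tau", "one_sided_alpha", "TXswitch",
    "n_simulations", "seed",
)


@dataclass(frozen=True)
class ScenarioConfig:
    n: int
    m1: float
    m2: float
    Ta: float
    Te: float
    tau: float
    r: float = 1.0
    shape: float = 1.0
    f1: float | None = None
    m0: float | None = None
    f2: float | None = None
    margin: float | None = None
    ps: float = 0.0
    rs: float | None = None
    rho_s: float | None = None
    s_dist: str | float | None = None
    censoring_rate: str | float = "AC.only"
    one_sided_alpha: float = 0.025
    TXswitch: str = "1to2"
    n_simulations: int = 5000
    seed: int = 12345

    def __post_init__(self) -> None:
        def bad(name: str, why: str):
            return ConfigError(f"invalid parameter {name!r}: {why}")

        if int(self.n) != self.n or self.n < 2:
            raise bad("n", "must be an integer >= 2")
        if self.r <= 0:
            raise bad("r", "must be > 0")
        for name in ("m1", "m2", "shape", "Te", "tau"):
            if getattr(self, name) <= 0:
                raise bad(name, "must be > 0")
        if self.Ta < 0:
            raise bad("Ta", "must be >= 0")
        if self.Te < self.Ta:
            raise bad("Te", "must be >= Ta")
        if self.tau > self.Te:
            raise bad("tau", "must be <= Te")
        if not 0 < self.one_sided_alpha < 1:
            raise bad("one_sided_alpha", "must lie in (0, 1)")
        if not 0 <= self.ps <= 1:
            raise bad("ps", "must lie in [0, 1]")
        if self.TXswitch not in ("1to2", "2to1"):
            raise bad("TXswitch", 'must be "1to2" or "2to1"')
        if self.n_simulations < 1:
            raise bad("n_simulations", "must be >= 1")
        if isinstance(self.censoring_rate, str):
            if self.censoring_rate != "AC.only":
                raise bad(
                    "censoring_rate", 'must be "AC.only" or a number in (0, 1)'
                )
        elif not 0 < self.censoring_rate < 1:
            raise bad("censoring_rate", 'must be "AC.only" or a number in (0, 1)')
        if isinstance(self.s_dist, str) and self.s_dist not in SWITCH_FAMILIES:
            raise bad(
                "s_dist", f"must be one of {SWITCH_FAMILIES} or a numeric constant"
            )
        if self.ps > 0 and self.s_dist is None:
            raise bad("s_dist", "required when ps > 0")
        if self.s_dist in ("beta", "gamma", "unif", "indepExp") and self.ps > 0:
            if self.rs is None:
                raise bad("rs", f"required for s_dist={self.s_dist!r}")
            if self.s_dist in ("beta", "gamma") and self.rho_s is None:
                raise bad("rho_s", f"required for s_dist={self.s_dist!r}")
        # margin option exclusivity (checked again, with values, at resolve time)
        active = [
            name
            for name, given in (
                ("f1", self.f1 is not None),
                ("f2/m0", self.f2 is not None or self.m0 is not None),
                ("margin", self.margin is not None),
            )
            if given
        ]
        if not active:
            raise ConfigError(
                "no margin option supplied: give f1, (f2 and m0), or margin"
            )
        if len(active) > 1:
            raise ConfigError(
                f"margin options are mutually exclusive; got {active}"
            )
        if (self.f2 is None) != (self.m0 is None):
            raise ConfigError("f2 and m0 must be supplied together")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        clean: dict = {}
        for key, value in raw.items():
            name = str(key).replace(".", "_")
            if name == "rhos":
                name = "rho_s"
            if name not in _FIELD_NAMES:
                raise ConfigError(f"unknown parameter {key!r}")
            clean[name] = value
        return cls(**clean)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def save(self, path) -> None:
        text = self.to_json() if str(path).endswith(".json") else yaml.safe_dump(
            self.to_dict(), sort_keys=False
        )
        Path(path).write_text(text)
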
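"""Simulation configuration: parameters, feature toggles, costs, seeds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

from .core import ConfigurationError, SigmoidSpec
from .interactions import NoiseSpec, PayoffMatrix

__all__ = ["SimConfig"]


@dataclass
class SimConfig:
    """All parameters of one simulation run.

    Defaults are the baseline condition: 500 agents, mortality 0.01 per
    iteration, 100,000 iterations, prisoner's-dilemma payoffs (3, 5, -1, 0),
    founder traits ~ Normal(0, 0.25), mutation ~ Normal(0, 0.04), courtship
    capped at 20 interactions per iteration, all mechanisms enabled,
    divorce allowed.
    """

    N: int = 500
    m: float = 0.01
    iterations: int = 100_000
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    c_cou: float = 0.0
    c_div: float = 4.0
    c_dec: float = 0.0
    enable_bookkeeping: bool = True
    enable_courtship: bool = True
    enable_deceit: bool = False
    divorce_mode: str = "allowed"
    sigmoid: SigmoidSpec = field(default_factory=SigmoidSpec)
    init_sigma: float = 0.25
    mut_sigma: float = 0.04
    max_courtship: int = 20
    seed: int = 0
    thin: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.N < 2:
            raise ConfigurationError("population size N must be at least 2")
        if not 0.0 <= self.m <= 1.0:
            raise ConfigurationError("mortality m must lie in [0, 1]")
        if self.iterations < 0:
            raise ConfigurationError("iterations must be nonnegative")
        for name in ("c_cou", "c_div", "c_dec"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost {name} must be nonnegative")
        if self.divorce_mode not in ("allowed", "prohibited"):
            raise ConfigurationError(f"unknown divorce_mode {self.divorce_mode!r}")
        if not self.init_sigma > 0:
            raise ConfigurationError("init_sigma must be positive")
        if self.mut_sigma < 0:
            raise ConfigurationError("mut_sigma must be nonnegative")
        if self.max_courtship < 0:
            raise ConfigurationError("max_courtship must be nonnegative")
        if self.thin < 1:
            raise ConfigurationError("thin must be at least 1")

    def replace(self, **changes: Any) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "m": self.m,
            "iterations": self.iterations,
            "payoff_R": self.payoffs.R,
            "payoff_T": self.payoffs.T,
            "payoff_S": self.payoffs.S,
            "payoff_P": self.payoffs.P,
            "noise_kind": self.noise.kind,
            "xi": self.noise.xi,
            "c_cou": self.c_cou,
            "c_div": self.c_div,
            "c_dec": self.c_dec,
            "enable_bookkeeping": self.enable_bookkeeping,
            "enable_courtship": self.enable_courtship,
            "enable_deceit": self.enable_deceit,
            "divorce_mode": self.divorce_mode,
            "sigmoid_kind": self.sigmoid.kind,
            "sigmoid_slope": self.sigmoid.a,
            "init_sigma": self.init_sigma,
            "mut_sigma": self.mut_sigma,
            "max_courtship": self.max_courtship,
            "seed": self.seed,
            "thin": self.thin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        payoffs = PayoffMatrix(
            R=d.pop("payoff_R", 3.0), T=d.pop("payoff_T", 5.0),
            S=d.pop("payoff_S", -1.0), P=d.pop("payoff_P", 0.0),
        )
        noise = NoiseSpec(kind=d.pop("noise_kind", "none"), xi=d.pop("xi", 0.0))
        sigmoid = SigmoidSpec(kind=d.pop("sigmoid_kind", "piecewise_linear"),
                              a=d.pop("sigmoid_slope", 10.0))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(payoffs=payoffs, noise=noise, sigmoid=sigmoid, **d)
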
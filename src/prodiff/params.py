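"""Model parameters and named parameter constellations.

A *constellation* bundles every knob of one simulation condition: the
acquisition sub-model (baseline learning rate lambda_b, social transmission
rate s, asocial-innovation switch A), the production sub-model (sigma, f, m,
rho, alpha), the population (N, degree k) and the behaviour rewards.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "AcquisitionParams",
    "ProductionParams",
    "Constellation",
    "reference_constellation",
    "table1_grid",
    "SENSITIVITY_VALUES",
]

#: Grid of production-rule values swept in the sensitivity analysis.
SENSITIVITY_VALUES = {
    "sigma": (0.25, 0.5, 0.75),
    "f": (0.33, 1.0, 3.0),
    "m": (10, 20, 30),
    "rho": (0.01, 0.10, 0.99),
    "alpha": (0.5, 1.0, 2.0),
}


@dataclass(frozen=True)
class AcquisitionParams:
    """Parameters of the social-transmission (hazard) sub-model.

    lambda_b : baseline learning rate per timestep (> 0).
    s        : social transmission rate (>= 0).
    asocial  : A in {0, 1}; 1 enables spontaneous asocial innovation.
    """

    lambda_b: float = 0.05
    s: float = 5.0
    asocial: int = 0

    def __post_init__(self) -> None:
        if self.lambda_b <= 0:
            raise ValueError("lambda_b must be > 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.asocial not in (0, 1):
            raise ValueError("asocial flag A must be 0 or 1")


@dataclass(frozen=True)
class ProductionParams:
    """Parameters of the reinforcement-learning production sub-model.

    sigma : social information bias in [0, 1] (weight on observed behaviour).
    f     : frequency-dependent production bias exponent (> 0); f > 1 is
            conformist, f < 1 anti-conformist.
    m     : memory window in timesteps (>= 1).
    rho   : recent experience bias in (0, 1) for the value update.
    alpha : risk appetite (> 0); small alpha -> near-deterministic choice of
            the highest-valued behaviour.
    """

    sigma: float = 0.5
    f: float = 1.0
    m: int = 10
    rho: float = 0.1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")
        if self.f <= 0:
            raise ValueError("f must be > 0")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class Constellation:
    """Full parameter set for one simulation condition."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    production: ProductionParams = field(default_factory=ProductionParams)
    n_agents: int = 24
    degree: int = 6
    r_a: float = 1.0
    r_b: float = 1.0
    label: str = "reference"

    def __post_init__(self) -> None:
        if self.r_a < 0 or self.r_b < 0:
            raise ValueError("rewards must be >= 0")
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")

    # -- flat config round-trip ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sigma": self.production.sigma,
            "f": self.production.f,
            "m": self.production.m,
            "rho": self.production.rho,
            "alpha": self.production.alpha,
            "lambda_b": self.acquisition.lambda_b,
            "s": self.acquisition.s,
            "A": self.acquisition.asocial,
            "N": self.n_agents,
            "k": self.degree,
            "r_a": self.r_a,
            "r_b": self.r_b,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Constellation":
        ref = cls()
        return cls(
            acquisition=AcquisitionParams(
                lambda_b=d.get("lambda_b", ref.acquisition.lambda_b),
                s=d.get("s", ref.acquisition.s),
                asocial=int(d.get("A", ref.acquisition.asocial)),
            ),
            production=ProductionParams(
                sigma=d.get("sigma", ref.production.sigma),
                f=d.get("f", ref.production.f),
                m=int(d.get("m", ref.production.m)),
                rho=d.get("rho", ref.production.rho),
                alpha=d.get("alpha", ref.production.alpha),
            ),
            n_agents=int(d.get("N", ref.n_agents)),
            degree=int(d.get("k", ref.degree)),
            r_a=d.get("r_a", ref.r_a),
            r_b=d.get("r_b", ref.r_b),
            label=d.get("label", "custom"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "Constellation":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Constellation":
        return cls.from_dict(json.loads(s))

    def with_production(self, **kwargs) -> "Constellation":
        """Copy with some production parameters replaced."""
        return replace(self, production=replace(self.production, **kwargs))

    def with_acquisition(self, **kwargs) -> "Constellation":
        """Copy with some acquisition parameters replaced."""
        return replace(self, acquisition=replace(self.acquisition, **kwargs))


def reference_constellation() -> Constellation:
    """The reference condition: sigma=0.5, f=1, m=10, rho=0.1, alpha=1,
    lambda_b=0.05, s=5, A=0, N=24, k=6, r_a=r_b=1."""
    return Constellation()


def table1_grid() -> list[Constellation]:
    """Full factorial sweep of the five production parameters.

    3 values each for sigma, f, m, rho and alpha -> 243 constellations, all
    other fields held at reference.
    """
    grid = []
    ref = reference_constellation()
    for sigma, f, m, rho, alpha in itertools.product(
        SENSITIVITY_VALUES["sigma"],
        SENSITIVITY_VALUES["f"],
        SENSITIVITY_VALUES["m"],
        SENSITIVITY_VALUES["rho"],
        SENSITIVITY_VALUES["alpha"],
    ):
        label = f"sigma={sigma},f={f},m={m},rho={rho},alpha={alpha}"
        grid.append(
            replace(
                ref,
                production=ProductionParams(sigma=sigma, f=f, m=m, rho=rho, alpha=alpha),
                label=label,
            )
        )
    return grid
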
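"""Small declarative distribution specs used by the simulators.

A spec is ``DistSpec(name, **params)`` or the equivalent mapping
``{"name": ..., <params>}``; sampling always goes through a caller-provided
numpy Generator so simulators stay deterministic under one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ConfigError

_SUPPORTED = {
    "constant": ("value",),
    "uniform": ("low", "high"),
    "normal": ("mean", "sd"),
    "lognormal": ("mean", "sigma"),
    "poisson": ("lam",),
    "negbinom": ("mean", "dispersion"),
    "beta": ("a", "b"),
}


@dataclass(frozen=True)
class DistSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _SUPPORTED:
            raise ConfigError(
                f"unknown distribution {self.name!r}; supported: {sorted(_SUPPORTED)}"
            )
        required = set(_SUPPORTED[self.name])
        given = set(self.params)
        if given != required:
            raise ConfigError(
                f"distribution {self.name!r} needs parameters {sorted(required)}, got {sorted(given)}"
            )
        p = self.params
        if self.name == "uniform" and not p["low"] <= p["high"]:
            raise ConfigError("uniform: low must be <= high")
        if self.name == "normal" and p["sd"] < 0:
            raise ConfigError("normal: sd must be >= 0")
        if self.name == "lognormal" and p["sigma"] < 0:
            raise ConfigError("lognormal: sigma must be >= 0")
        if self.name == "poisson" and p["lam"] < 0:
            raise ConfigError("poisson: lam must be >= 0")
        if self.name == "negbinom" and (p["mean"] < 0 or p["dispersion"] < 0):
            raise ConfigError("negbinom: mean and dispersion must be >= 0")
        if self.name == "beta" and (p["a"] <= 0 or p["b"] <= 0):
            raise ConfigError("beta: shape parameters must be > 0")

    @classmethod
    def coerce(cls, spec) -> "DistSpec":
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, dict):
            d = dict(spec)
            try:
                name = d.pop("name")
            except KeyError:
                raise ConfigError("distribution spec mapping needs a 'name' key") from None
            params = d.pop("params", None)
            if params is None:
                params = d
            return cls(name=name, params=dict(params))
        raise ConfigError(f"cannot interpret {spec!r} as a distribution spec")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        p = self.params
        if self.name == "constant":
            return np.full(size, p["value"], dtype=float)
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.name == "normal":
            return rng.normal(p["mean"], p["sd"], size=size)
        if self.name == "lognormal":
            return rng.lognormal(p["mean"], p["sigma"], size=size)
        if self.name == "poisson":
            return rng.poisson(p["lam"], size=size).astype(float)
        if self.name == "negbinom":
            mean, alpha = p["mean"], p["dispersion"]
            if alpha == 0:
                return rng.poisson(mean, size=size).astype(float)
            r = 1.0 / alpha
            return rng.negative_binomial(r, r / (r + mean), size=size).astype(float)
        if self.name == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}
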
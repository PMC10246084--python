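"""Structured-text run configuration (YAML) and its round-trip to model objects."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .demography import (Demography, DispersalSpec, KernelSpec, RateFunction,
                         rate_function)
from .domain import Domain

__all__ = ["RunConfig", "load_config", "build_demography", "build_dispersal",
           "build_domain"]

_RATE_ALIASES = {
    "logistic": ("logistic_F",),
    "constant_1": ("constant", 1.0),
    "zero": ("constant", 0.0),
}


def _parse_rate(block) -> RateFunction:
    if isinstance(block, str):
        if block in _RATE_ALIASES:
            name, *params = _RATE_ALIASES[block]
            return rate_function(name, *params)
        return rate_function(block)
    name = block["name"]
    params = block.get("params", [])
    return rate_function(name, *params)


def _rate_to_dict(rf: RateFunction):
    return {"name": rf.name, "params": list(rf.params)}


def _parse_kernel(block, dim: int) -> KernelSpec:
    return KernelSpec(block.get("family", "gaussian"),
                      float(block.get("scale", 1.0)), dim)


@dataclass
class RunConfig:
    """model (demography, dispersal, domain) + run + output blocks."""

    data: dict = field(default_factory=dict)

    @property
    def seed(self) -> int:
        run = self.data.get("run", {})
        if "seed" not in run:
            raise ValueError("run.seed is mandatory for stochastic runs")
        return int(run["seed"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(yaml.safe_load(text) or {})


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


def build_domain(cfg: RunConfig) -> Domain:
    d = cfg.data.get("domain", {})
    return Domain(int(d.get("dim", 1)),
                  tuple(float(v) for v in d.get("lengths", [1.0])),
                  d.get("boundary", "periodic"))


def build_demography(cfg: RunConfig) -> Demography:
    dm = cfg.data["demography"]
    dom = build_domain(cfg)
    kernels = {key: _parse_kernel(dm.get("kernels", {}).get(key, {}), dom.dim)
               for key in ("gamma", "r", "F")}
    kwargs = {}
    if "m_range" in dm:
        kwargs["m_range"] = tuple(float(v) for v in dm["m_range"])
    return Demography(_parse_rate(dm["gamma"]), _parse_rate(dm["r"]),
                      _parse_rate(dm["F"]), float(dm["theta"]),
                      float(dm["N"]), kernels, **kwargs)


def build_dispersal(cfg: RunConfig) -> DispersalSpec:
    dm = cfg.data["demography"]
    dd = cfg.data.get("dispersal", {})
    dom = build_domain(cfg)
    return DispersalSpec(theta=float(dm["theta"]), dim=dom.dim,
                         mean=dd.get("b"),
                         sigma2=float(dd["sigma2"]) if "sigma2" in dd else None,
                         cov=dd.get("C"))
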
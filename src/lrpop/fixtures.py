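"""Initial conditions: point clouds and density profiles."""

from __future__ import annotations

import numpy as np

from .domain import Domain
from .fields import DensityField
from .pde import WaveFrameModel
from .population import PointPopulation

__all__ = ["poisson_uniform", "block_population", "block_field",
           "wave_profile_field", "make_fixture"]


def poisson_uniform(N: float, density: float, domain: Domain,
                    rng: np.random.Generator,
                    sub_box: tuple | None = None) -> PointPopulation:
    """Homogeneous Poisson cloud at scaled density (N·density per unit volume).

    ``sub_box`` restricts the support to (lo, hi) corner vectors; by default
    the whole domain is filled.
    """
    if sub_box is None:
        lo = np.zeros(domain.dim)
        hi = np.asarray(domain.lengths, dtype=float)
    else:
        lo = np.asarray(sub_box[0], dtype=float).reshape(-1)
        hi = np.asarray(sub_box[1], dtype=float).reshape(-1)
    vol = float(np.prod(hi - lo))
    n = rng.poisson(N * density * vol)
    pos = rng.uniform(lo, hi, size=(n, domain.dim))
    return PointPopulation(pos, N, domain)


def block_population(N: float, domain: Domain, rng: np.random.Generator,
                     edge: float, density: float = 1.0) -> PointPopulation:
    """Density ``density`` on [0, edge) (per axis 0), zero elsewhere."""
    if edge <= 0:
        return PointPopulation(np.empty((0, domain.dim)), N, domain)
    hi = np.asarray(domain.lengths, dtype=float).copy()
    hi[0] = min(edge, hi[0])
    return poisson_uniform(N, density, domain, rng,
                           sub_box=(np.zeros(domain.dim), hi))


def block_field(length: float, dx: float, edge: float,
                boundary: str = "neumann", x0: float = 0.0,
                height: float = 1.0) -> DensityField:
    """Heaviside profile: ``height`` for x < edge, 0 beyond."""
    G = int(round(length / dx))
    x = x0 + dx * np.arange(G)
    return DensityField(np.where(x < edge, height, 0.0), dx, x0, boundary)


def wave_profile_field(model: WaveFrameModel, length: float, dx: float,
                       boundary: str = "neumann",
                       x0: float = 0.0) -> DensityField:
    """Sampled closed-form (or relaxed) travelling-wave profile."""
    G = int(round(length / dx))
    x = x0 + dx * np.arange(G)
    return DensityField(model.profile(x), dx, x0, boundary)


def make_fixture(kind: str, params: dict, rng: np.random.Generator):
    """Dispatch on kind ∈ {poisson_uniform, block, wave_profile}."""
    if kind == "poisson_uniform":
        dom = params.get("domain") or Domain(
            params.get("dim", 1), tuple(params["lengths"]),
            params.get("boundary", "periodic"))
        return poisson_uniform(params["N"], params.get("density", 1.0),
                               dom, rng, params.get("sub_box"))
    if kind == "block":
        if "N" in params:
            dom = params.get("domain") or Domain(
                params.get("dim", 1), tuple(params["lengths"]),
                params.get("boundary", "periodic"))
            return block_population(params["N"], dom, rng, params["edge"],
                                    params.get("density", 1.0))
        return block_field(params["length"], params["dx"], params["edge"],
                           params.get("boundary", "neumann"),
                           params.get("x0", 0.0), params.get("height", 1.0))
    if kind == "wave_profile":
        model = WaveFrameModel(params["model"], s=params.get("s", 0.5),
                               x0=params.get("wave_x0", 0.0))
        return wave_profile_field(model, params["length"], params["dx"],
                                  params.get("boundary", "neumann"),
                                  params.get("x0", 0.0))
    raise ValueError(f"unknown fixture kind {kind!r}")
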
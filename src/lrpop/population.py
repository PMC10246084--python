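"""Atomic population states.

The population at time t is a purely atomic measure with one atom of mass
1/N per individual; its total mass is n/N, the number of individuals
relative to the nominal occupancy of N individuals per unit volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .domain import Domain

__all__ = ["PointPopulation", "Trajectory"]


@dataclass
class PointPopulation:
    """Locations of the n individuals, each carrying mass 1/N."""

    positions: np.ndarray  # (n, d)
    N: float
    domain: Domain
    time: float = 0.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, self.domain.dim)
        if pos.shape[1] != self.domain.dim:
            raise ValueError(
                f"positions have dim {pos.shape[1]}, domain has {self.domain.dim}")
        if self.N <= 0:
            raise ValueError("N must be positive")
        self.positions = self.domain.wrap(pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def total_mass(self) -> float:
        """⟨1, η⟩ = n/N."""
        return self.n / self.N

    def with_positions(self, positions: np.ndarray) -> "PointPopulation":
        return replace(self, positions=positions)


@dataclass
class Trajectory:
    """Recorded snapshots of a simulation run."""

    times: list[float] = field(default_factory=list)
    snapshots: list[PointPopulation] = field(default_factory=list)
    seed: int | None = None
    config: dict | None = None

    def append(self, pop: PointPopulation) -> None:
        if self.times and pop.time <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(pop.time)
        self.snapshots.append(pop)

    @property
    def total_mass(self) -> np.ndarray:
        return np.array([p.total_mass for p in self.snapshots])

    @property
    def counts(self) -> np.ndarray:
        return np.array([p.n for p in self.snapshots])
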
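"""Gridded density fields for the PDE scaling limits."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DensityField"]


@dataclass
class DensityField:
    """A nonnegative density φ on a regular 1D (or 2D) lattice.

    ``x0`` is the coordinate of the first grid point; 1D grids have shape
    (G,), 2D grids (Gx, Gy) with equal spacing in both directions.
    """

    values: np.ndarray
    dx: float
    x0: float = 0.0
    boundary: str = "periodic"   # periodic | neumann
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.boundary not in ("periodic", "neumann"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def grid(self) -> np.ndarray:
        """1D coordinate array (first axis for 2D fields)."""
        return self.x0 + self.dx * np.arange(self.values.shape[0])

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.dx ** self.values.ndim)

    def interp(self, x) -> np.ndarray:
        """Linear interpolation of a 1D field at positions x."""
        if self.values.ndim != 1:
            raise ValueError("interp supports 1D fields")
        x = np.asarray(x, dtype=float)
        G = self.values.size
        pos = (x - self.x0) / self.dx
        if self.boundary == "periodic":
            pos = np.mod(pos, G)
            i0 = np.floor(pos).astype(int)
            frac = pos - i0
            i1 = (i0 + 1) % G
            return (1 - frac) * self.values[i0] + frac * self.values[i1]
        return np.interp(x, self.grid, self.values)

    def copy(self, **kw) -> "DensityField":
        out = replace(self, **kw)
        out.values = np.array(out.values, dtype=float, copy=True)
        return out
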
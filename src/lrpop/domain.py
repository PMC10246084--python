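"""Spatial domains: dimension, extent, and boundary handling.

The default habitat is a periodic box (torus), which matches the
homogeneous-equilibrium analyses and avoids edge effects; distances are
measured through the minimal image.  An ``unbounded`` domain is provided
for wave-frame and free-space computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Domain"]


@dataclass(frozen=True)
class Domain:
    """A 1D or 2D habitat.

    Parameters
    ----------
    dim
        Spatial dimension, 1 or 2.
    lengths
        Box side lengths (ignored for ``boundary="unbounded"``).
    boundary
        ``"periodic"`` (default) or ``"unbounded"``.
    """

    dim: int = 1
    lengths: tuple[float, ...] = (1.0,)
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        if self.boundary not in ("periodic", "unbounded"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if len(self.lengths) != self.dim:
            object.__setattr__(self, "lengths", tuple(self.lengths) * self.dim
                               if len(self.lengths) == 1 else self.lengths)
        if len(self.lengths) != self.dim:
            raise ValueError("lengths must match dim")
        if self.boundary == "periodic" and any(L <= 0 for L in self.lengths):
            raise ValueError("periodic domain needs positive lengths")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map positions into the fundamental box [0, L)^d (periodic only)."""
        x = np.asarray(x, dtype=float)
        if self.boundary != "periodic":
            return x
        return np.mod(x, np.asarray(self.lengths))

    def displacement(self, dx: np.ndarray) -> np.ndarray:
        """Minimal-image displacement vector(s)."""
        dx = np.asarray(dx, dtype=float)
        if self.boundary != "periodic":
            return dx
        L = np.asarray(self.lengths)
        return dx - L * np.round(dx / L)
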
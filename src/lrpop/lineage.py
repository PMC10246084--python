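"""Backward-in-time ancestral lineage diffusions.

In the deterministic (high-density) limit with density φ, the spatial path
of the ancestry of a sampled individual is a diffusion.  With isotropic
dispersal (C = σ²I) its generator is

    ℒf = (σ²/2) r γ [Δf + (2∇log(γφ) − 2b/σ²)·∇f] ,

so lineages run at speed rγ (the local rate of production of mature
offspring) and are drawn up the gradient of log(γφ) (towards high
fecundity), not up the population gradient itself.  In the frame co-moving
with a travelling wave w at speed c the generator becomes time-homogeneous:

    ℒf = (σ²/2) r γ [Δf + 2∇log(γw)·∇f] + (c − rγb)·∇f .

For a 1D generator a(x)∂xx + μ(x)∂x the speed-measure density is
m(x) ∝ a(x)^{-1} exp(∫ μ/a); when integrable its normalization is the
unique stationary distribution of the lineage position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad

from .fields import DensityField
from .pde import WaveFrameModel

__all__ = [
    "LineageCoeffs", "LineagePath", "StationaryResult",
    "lineage_coeffs", "lineage_coeffs_lab", "simulate_lineage",
    "stationary_density", "reproductive_value", "HistoryExhaustedError",
    "UndefinedCoefficientError",
]

_LOG_FLOOR = 1e-300


class HistoryExhaustedError(RuntimeError):
    """A simulated path left the support of the stored density history."""


class UndefinedCoefficientError(ValueError):
    """Coefficients requested where the density vanishes."""


@dataclass
class LineagePath:
    """Backward times s_k (increasing from 0 at the sampling time) and positions."""

    s: np.ndarray
    positions: np.ndarray   # (n_steps, ...) or (n_paths, n_steps)
    frame: str = "wave"


@dataclass
class LineageCoeffs:
    """1D diffusion coefficients: generator a(x)∂xx + drift(x)∂x.

    ``a`` is the second-order coefficient ((σ²/2)rγ); the matching SDE is
    dX = drift dt + √(2a) dW.  ``bounds`` limit where coefficients are
    defined (e.g. behind a sharp front).
    """

    a_fn: callable
    drift_fn: callable
    frame: str
    bounds: tuple[float, float] = (-np.inf, np.inf)
    reflect_at: float | None = None
    reflect_bounds: bool = False

    def a(self, x):
        return np.asarray(self.a_fn(np.asarray(x, dtype=float)))

    def drift(self, x):
        return np.asarray(self.drift_fn(np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# coefficient assembly


def lineage_coeffs(model: WaveFrameModel) -> LineageCoeffs:
    """Wave-frame lineage coefficients for the three reference waves.

    Fisher-KPP:      ∂xx + (2w′/w + 2)∂x — drift → +2 in the bulk, → 0 in
                     the tip (w ~ e^{−x});
    Allen–Cahn(s):   ∂xx + (s − 2eˣ/(1+eˣ))∂x;
    porous-medium:   (1−e^{ξ/2})∂xx + (1 − 2e^{ξ/2})∂x on ξ < 0 — the
                     diffusion coefficient vanishes continuously at the front.
    """
    s2 = model.sigma2
    if model.kind == "fisher_kpp":
        h = 1e-5

        def drift(x):
            w = np.maximum(model.profile(x), _LOG_FLOOR)
            wp = (model.profile(x + h) - model.profile(x - h)) / (2 * h)
            return s2 * wp / w + model.c

        return LineageCoeffs(lambda x: np.full_like(np.asarray(x, float),
                                                    s2 / 2.0),
                             drift, "wave")
    if model.kind == "allen_cahn":
        def drift(x):
            z = np.asarray(x, dtype=float) - model.x0
            return model.s - s2 * np.exp(z) / (1.0 + np.exp(z))

        return LineageCoeffs(lambda x: np.full_like(np.asarray(x, float),
                                                    s2 / 2.0),
                             drift, "wave")
    # pme_logistic: r = 1, γ = w, so a = (σ²/2)·w and
    # drift = (σ²/2)·w·2(w²)′/w² + c = 2σ²w′/... = 1 − 2e^{ξ/2} for σ²=2, c=1
    def a_fn(x):
        z = np.asarray(x, dtype=float) - model.x0
        return (s2 / 2.0) * np.maximum(1.0 - np.exp(np.minimum(z, 0.0) / 2.0),
                                       0.0)

    def drift(x):
        z = np.asarray(x, dtype=float) - model.x0
        return model.c - s2 * np.exp(np.minimum(z, 0.0) / 2.0)

    return LineageCoeffs(a_fn, drift, "wave", bounds=(-np.inf, model.x0),
                         reflect_at=model.x0 - 1e-6)


def lineage_coeffs_lab(phi: DensityField, r_vals, gamma_vals,
                       sigma2: float = 2.0, b: float = 0.0) -> LineageCoeffs:
    """Lab-frame coefficients from a gridded stationary density φ.

    ``r_vals`` / ``gamma_vals`` are arrays on the grid of φ (or scalars).
    ∇log(γφ) is computed by central differences of the log-transformed
    values with floor 1e-300; requesting coefficients where γφ is at the
    floor raises rather than clips.
    """
    grid = phi.grid
    rv = np.broadcast_to(np.asarray(r_vals, dtype=float), grid.shape)
    gv = np.broadcast_to(np.asarray(gamma_vals, dtype=float), grid.shape)
    gphi = gv * phi.values
    if np.any(gphi <= 0):
        raise UndefinedCoefficientError("gamma*phi must be positive on the grid")
    loggp = np.log(np.maximum(gphi, _LOG_FLOOR))
    dlog = np.gradient(loggp, phi.dx)
    rg = rv * gv
    drift_vals = (sigma2 / 2.0) * rg * (2.0 * dlog - 2.0 * b / sigma2)
    a_vals = (sigma2 / 2.0) * rg
    lo, hi = grid[0], grid[-1]

    def _interp(vals):
        def f(x):
            x = np.asarray(x, dtype=float)
            if np.any((x < lo - phi.dx) | (x > hi + phi.dx)):
                raise HistoryExhaustedError("position left the stored grid")
            return np.interp(x, grid, vals)
        return f

    return LineageCoeffs(_interp(a_vals), _interp(drift_vals), "lab",
                         bounds=(lo, hi))


# ---------------------------------------------------------------------------
# simulation


def simulate_lineage(coeffs: LineageCoeffs, x0: float, S: float, dt: float,
                     rng: np.random.Generator, n_paths: int = 1,
                     record_every: float | None = None) -> LineagePath:
    """Euler–Maruyama ensemble for dX = drift dt + √(2a) dW over backward time S.

    Paths are reflected at ``coeffs.reflect_at`` (degenerate front boundary)
    when set.
    """
    n_steps = int(round(S / dt))
    stride = 1 if record_every is None else max(int(round(record_every / dt)), 1)
    x = np.full(n_paths, float(x0))
    out = [x.copy()]
    s_rec = [0.0]
    sq = math.sqrt(dt)
    for k in range(1, n_steps + 1):
        a = np.maximum(coeffs.a(x), 0.0)
        x = x + coeffs.drift(x) * dt \
            + np.sqrt(2.0 * a) * sq * rng.standard_normal(n_paths)
        if coeffs.reflect_at is not None:
            over = x > coeffs.reflect_at
            x[over] = 2.0 * coeffs.reflect_at - x[over]
        if coeffs.reflect_bounds:
            lo, hi = coeffs.bounds
            if np.isfinite(lo):
                x = np.where(x < lo, 2.0 * lo - x, x)
            if np.isfinite(hi):
                x = np.where(x > hi, 2.0 * hi - x, x)
        if k % stride == 0:
            out.append(x.copy())
            s_rec.append(k * dt)
    return LineagePath(np.asarray(s_rec), np.vstack(out).T, coeffs.frame)


# ---------------------------------------------------------------------------
# stationary analysis


@dataclass
class StationaryResult:
    grid: np.ndarray
    density: np.ndarray | None   # None when the speed measure is non-integrable
    integrable: bool
    note: str = ""

    def cdf(self, x):
        if not self.integrable:
            raise ValueError("no stationary distribution")
        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        c /= c[-1]
        return np.interp(x, self.grid, c)


def stationary_density(source, grid=None) -> StationaryResult:
    """Normalized speed-measure density m(x) ∝ a(x)^{-1} exp(∫ drift/a).

    ``source`` may be a :class:`WaveFrameModel` (closed forms used for the
    Allen–Cahn and porous-medium waves; the Fisher-KPP speed measure is
    non-integrable and reported as such) or a :class:`LineageCoeffs`
    (numerical quadrature on the grid).  Non-integrability is a reported
    outcome, not an error.
    """
    if isinstance(source, WaveFrameModel):
        if source.kind == "fisher_kpp":
            g = np.linspace(-30, 30, 601) if grid is None else np.asarray(grid)
            return StationaryResult(g, None, False,
                                    "speed measure ∝ e^{2x} w² is not integrable")
        if source.kind == "allen_cahn":
            g = (np.linspace(-40, 40, 4001) if grid is None
                 else np.asarray(grid, dtype=float))
            z = g - source.x0
            log_dens = source.s * z - 2.0 * np.logaddexp(0.0, z)
            dens = np.exp(log_dens)
            Z, _ = quad(lambda x: math.exp(source.s * x
                                           - 2.0 * np.logaddexp(0.0, x)),
                        -np.inf, np.inf)
            return StationaryResult(g, dens / Z, True)
        # porous-medium: m(ξ) ∝ e^ξ(1 − e^{ξ/2}) on ξ<0, normalization 3
        g = (np.linspace(-40, 0, 4001) if grid is None
             else np.asarray(grid, dtype=float))
        z = np.minimum(g - source.x0, 0.0)
        dens = 3.0 * np.exp(z) * (1.0 - np.exp(z / 2.0))
        return StationaryResult(g, dens, True)
    coeffs: LineageCoeffs = source
    if grid is None:
        raise ValueError("a grid is required for numerical coefficients")
    g = np.asarray(grid, dtype=float)
    a = np.maximum(coeffs.a(g), _LOG_FLOOR)
    mu = coeffs.drift(g)
    logm = cumulative_trapezoid(mu / a, g, initial=0.0) - np.log(a)
    logm -= logm.max()
    m = np.exp(logm)
    # integrability heuristic: the unnormalized density must decay at the
    # accessible ends of the grid
    edge = max(m[0], m[-1])
    integrable = edge < 1e-3 or (coeffs.reflect_at is not None and m[0] < 1e-3)
    if not integrable:
        return StationaryResult(g, None, False,
                                "speed measure does not decay on the grid")
    Z = np.trapezoid(m, g)
    return StationaryResult(g, m / Z, True)


def reproductive_value(source, phi, grid=None) -> StationaryResult:
    """Per-capita long-term reproductive value ∝ π(x)/φ(x) (normalized).

    ``phi`` is the stationary population density: a callable, a
    :class:`DensityField`, or an array on the grid of the stationary
    density.  Propagates non-integrability of π.
    """
    pi = stationary_density(source, grid)
    if not pi.integrable:
        return StationaryResult(pi.grid, None, False, pi.note)
    if callable(phi):
        pv = np.asarray(phi(pi.grid), dtype=float)
    elif isinstance(phi, DensityField):
        pv = phi.interp(pi.grid)
    else:
        pv = np.broadcast_to(np.asarray(phi, dtype=float), pi.grid.shape)
    if np.any(pv <= 0):
        raise UndefinedCoefficientError("phi must be positive on the grid")
    v = pi.density / pv
    Z = np.trapezoid(v, pi.grid)
    return StationaryResult(pi.grid, v / Z, True)
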
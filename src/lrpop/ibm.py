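"""Forward simulation of the scaled individual-based population process.

Two drivers are provided.  ``gillespie_run`` is the exact event-driven
simulation: each individual carries a birth rate θγ(x, ρ_γ*η(x)) and a
death rate θμ_θ(x, ·) in scaled time, and all rates are recomputed exactly
at every event (correctness over speed).  ``discrete_step`` is the
discrete-time variant: within one step of length dt every individual
independently reproduces with probability 1 − exp(−θγ dt) and dies with
probability 1 − exp(−θμ_θ dt), all probabilities read from the
start-of-step population, so the update is order-independent.

A juvenile lands at y = x + b/θ + Kz/√θ and establishes with probability
r(y, ρ_r*η(y)) evaluated on the pre-birth population: maturity is
instantaneous and juveniles are never counted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .demography import (Demography, DispersalSpec, KernelSpec,
                         kernel_cell_average, local_density,
                         sample_dispersal)
from .fields import DensityField
from .population import PointPopulation, Trajectory

__all__ = ["gillespie_run", "discrete_step", "binned_density",
           "smoothed_density_at", "ExplosionError"]


class ExplosionError(RuntimeError):
    """Population exceeded the configured hard cap."""


def _default_nmax(pop: PointPopulation) -> int:
    return max(1000, int(100 * pop.N * pop.domain.volume))


# ---------------------------------------------------------------------------
# density evaluation


def smoothed_density_at(pop: PointPopulation, k: KernelSpec, points,
                        method: str = "auto", dx: float | None = None):
    """Kernel-smoothed density at many points.

    ``method="direct"`` is the exact pairwise sum; ``"fft"`` deposits atoms
    on a grid (cloud-in-cell), convolves with the kernel by FFT and
    interpolates — O(dx²)-accurate and much faster for large populations on
    periodic 1D domains.  ``"auto"`` switches to FFT when the pairwise cost
    gets large.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if method == "auto":
        use_fft = (pop.domain.dim == 1 and pop.domain.boundary == "periodic"
                   and pop.n * points.shape[0] > 250_000)
        method = "fft" if use_fft else "direct"
    if method == "direct":
        return local_density(pop, k, points)
    field = binned_density(pop, dx or k.scale / 20.0, k)
    return field.interp(points[:, 0])


def binned_density(pop: PointPopulation, dx: float, k: KernelSpec) -> DensityField:
    """Deposit atom masses on a grid and convolve with the kernel by FFT.

    Periodic 1D domains only.  The field integrates to the population mass
    n/N up to floating-point roundoff (the kernel is normalized on the
    discrete grid).
    """
    if pop.domain.dim != 1 or pop.domain.boundary != "periodic":
        raise ValueError("binned_density requires a periodic 1D domain")
    if dx > k.scale:
        raise ValueError("grid spacing dx must not exceed the kernel scale")
    L = pop.domain.lengths[0]
    G = int(round(L / dx))
    dx = L / G
    h = np.zeros(G)
    if pop.n:
        pos = pop.positions[:, 0] / dx
        i0 = np.floor(pos).astype(int) % G
        frac = pos - np.floor(pos)
        np.add.at(h, i0, (1.0 - frac))
        np.add.at(h, (i0 + 1) % G, frac)
    h /= pop.N * dx
    xs = np.arange(G) * dx
    xs = np.minimum(xs, L - xs)  # minimal-image distance to 0
    rho = kernel_cell_average(k, xs, dx)
    s = rho.sum() * dx
    if s > 0:
        rho = rho / s  # renormalize on the discrete torus
    vals = np.fft.irfft(np.fft.rfft(h) * np.fft.rfft(rho), n=G) * dx
    return DensityField(np.maximum(vals, 0.0), dx=dx, x0=0.0,
                        boundary="periodic", time=pop.time)


def _three_densities(pop: PointPopulation, dem: Demography, points,
                     method: str = "auto"):
    """(m_γ, m_r, m_F) at the given points, sharing work for equal kernels."""
    cache: dict[KernelSpec, np.ndarray] = {}
    out = []
    for key in ("gamma", "r", "F"):
        k = dem.kernels[key]
        if k not in cache:
            cache[k] = np.atleast_1d(smoothed_density_at(pop, k, points, method))
        out.append(cache[k])
    return tuple(out)


# ---------------------------------------------------------------------------
# exact event-driven simulation


def gillespie_run(pop0: PointPopulation, dem: Demography, disp: DispersalSpec,
                  T: float, rng: np.random.Generator,
                  record_every: float = 0.1, n_max: int | None = None,
                  density_method: str = "auto") -> Trajectory:
    """Exact simulation of the scaled birth–death process up to scaled time T."""
    if n_max is None:
        n_max = _default_nmax(pop0)
    pop = pop0.with_positions(pop0.positions.copy())
    traj = Trajectory()
    traj.append(pop.with_positions(pop.positions.copy()))
    t = pop.time
    next_record = t + record_every
    theta = dem.theta
    while t < T:
        n = pop.n
        if n == 0:
            # absorbing: pad the record with empty snapshots
            while next_record <= T + 1e-12:
                traj.append(PointPopulation(np.empty((0, pop.domain.dim)),
                                            pop.N, pop.domain, time=next_record))
                next_record += record_every
            break
        if n > n_max:
            raise ExplosionError(
                f"population size {n} exceeded n_max={n_max} at t={t:.4g}; "
                "check that mu_theta regulates growth for these parameters")
        mg, mr, mf = _three_densities(pop, dem, pop.positions, density_method)
        birth = theta * dem.gamma_fn(pop.positions, mg)
        death = theta * np.asarray(
            dem.mu_theta(pop.positions, mr, mg, mf))
        rates = np.concatenate([birth, death])
        R = rates.sum()
        if R <= 0:
            t = T
            while next_record <= T + 1e-12:
                pop.time = next_record
                traj.append(pop.with_positions(pop.positions.copy()))
                next_record += record_every
            break
        dt = rng.exponential(1.0 / R)
        while next_record <= min(t + dt, T) + 1e-12:
            snap = pop.with_positions(pop.positions.copy())
            snap.time = next_record
            traj.append(snap)
            next_record += record_every
        t += dt
        if t >= T:
            break
        i = rng.choice(2 * n, p=rates / R)
        if i < n:  # birth proposal from parent i
            y = sample_dispersal(disp, pop.positions[i], rng, domain=pop.domain)
            mr_y = smoothed_density_at(pop, dem.kernels["r"], y, density_method)
            if rng.random() < float(np.atleast_1d(dem.r_fn(y, mr_y))[0]):
                pop = pop.with_positions(
                    np.vstack([pop.positions, y[None, :]]))
        else:  # death
            j = i - n
            pop = pop.with_positions(np.delete(pop.positions, j, axis=0))
        pop.time = t
    return traj


# ---------------------------------------------------------------------------
# discrete-time simulation


def discrete_step(pop: PointPopulation, dem: Demography, disp: DispersalSpec,
                  dt: float, rng: np.random.Generator,
                  density_method: str = "auto",
                  warn_threshold: float = 0.5) -> PointPopulation:
    """One synchronous step of length dt (scaled time).

    Birth and death decisions use the same start-of-step densities; all
    offspring are appended after all decisions.  With the porous-medium
    parameterization (r≡1, γ=m, F=1−m) the probabilities reduce to the
    per-θ-time forms p_birth(m) = 1−e^{−m dτ}, p_death = 1−e^{−(m(1+1/θ)−1/θ)dτ}
    with dτ = θ dt.
    """
    if pop.n == 0:
        out = pop.with_positions(pop.positions.copy())
        out.time = pop.time + dt
        return out
    theta = dem.theta
    mg, mr, mf = _three_densities(pop, dem, pop.positions, density_method)
    g = np.asarray(dem.gamma_fn(pop.positions, mg))
    mu = np.asarray(dem.mu_theta(pop.positions, mr, mg, mf))
    rate_scale = dt * theta * max(g.max(initial=0.0), mu.max(initial=0.0))
    if rate_scale > warn_threshold:
        warnings.warn(f"dt*theta*rate = {rate_scale:.3g} is not small; "
                      "discrete-time probabilities are biased", stacklevel=2)
    p_birth = 1.0 - np.exp(-g * theta * dt)
    p_death = 1.0 - np.exp(-mu * theta * dt)
    gives_birth = rng.random(pop.n) < p_birth
    dies = rng.random(pop.n) < p_death
    offspring = []
    if gives_birth.any():
        parents = pop.positions[gives_birth]
        if callable(disp.mean) or callable(disp.cov):
            disp_draws = np.vstack([
                sample_dispersal(disp, x, rng, domain=pop.domain)
                for x in parents])
        else:  # homogeneous dispersal: draw all displacements at once
            K = disp.cholesky(parents[0])
            z = rng.standard_normal(parents.shape)
            b = np.asarray(disp.b(parents[0]), float).reshape(-1)
            disp_draws = pop.domain.wrap(
                parents + b[None, :] / disp.theta
                + (z @ K.T) / math.sqrt(disp.theta))
        mr_y = np.atleast_1d(smoothed_density_at(
            pop, dem.kernels["r"], disp_draws, density_method))
        keep = rng.random(len(disp_draws)) < np.asarray(
            dem.r_fn(disp_draws, mr_y))
        offspring = disp_draws[keep]
    survivors = pop.positions[~dies]
    new_pos = np.vstack([survivors, offspring]) if len(offspring) else survivors
    out = PointPopulation(new_pos, pop.N, pop.domain, time=pop.time + dt)
    return out
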
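"""Linear stability of the spatially constant equilibrium: the clumping
dispersion relation.

With spatially homogeneous parameters and 𝓑 = σ²Δ (dispersal variance
2σ²), a constant density φ0 with F(φ0) = 0 and F′(φ0) < 0 is an
equilibrium of the nonlocal equation.  Linearizing φ = φ0 + ψ and Fourier
transforming gives a per-mode growth rate

    λ(u) = −u²σ²φ0 r0 γ0′ ρ̃_γ(u) − u²σ² r0 γ0 + φ0 F0′ ρ̃_F(u) ,

where ρ̃ is the kernel transform normalized so ρ̃(0) = 1 (the factor that
the convolution theorem actually produces, equal to 2π·kernel_fourier).
A positive λ on a band of wavenumbers means the homogeneous state sheds a
pattern with wavelength near 2π/u*, u* the fastest-growing mode: with a
top-hat competition kernel of half-width ε, ρ̃_F(u) = sin(εu)/(εu) goes
negative on (π/ε, 2π/ε), so short-range dispersal (σ²/ε² small) carves an
unstable band there — discrete clumps spaced by roughly the interaction
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .demography import Demography, KernelSpec, kernel_fourier

__all__ = ["DispersionSpec", "DispersionResult", "equilibrium_density",
           "growth_rate", "unstable_band", "predicted_vs_observed_wavelength",
           "NoEquilibriumError"]


class NoEquilibriumError(ValueError):
    pass


@dataclass
class DispersionSpec:
    """Linearization data around the constant equilibrium φ0.

    ``sigma2`` is the diffusivity (𝓑 = σ²Δ; dispersal variance 2σ²).
    ``gamma0p`` and ``F0p`` are ∂_m γ and ∂_m F at φ0; F0p < 0 is required
    (stable nonspatial equilibrium).
    """

    phi0: float
    r0: float = 1.0
    gamma0: float = 1.0
    gamma0p: float = 0.0
    F0p: float = -1.0
    sigma2: float = 1.0
    kernel_gamma: KernelSpec = field(
        default_factory=lambda: KernelSpec("gaussian", 1.0, 1))
    kernel_F: KernelSpec = field(
        default_factory=lambda: KernelSpec("gaussian", 1.0, 1))

    def __post_init__(self) -> None:
        if self.F0p >= 0:
            raise ValueError("F'(phi0) must be negative (stable equilibrium)")


@dataclass
class DispersionResult:
    u: np.ndarray
    lam: np.ndarray
    unstable_intervals: list[tuple[float, float]]
    u_star: float | None       # argmax of λ over the unstable set, if any


def equilibrium_density(dem: Demography | None = None, *, F=None, r=None,
                        gamma=None, mu=None, m_max: float = 10.0,
                        m_min: float = 1e-8) -> float:
    """Root of F(m) = 0 (equivalently rγ = μ) with F′ < 0, by bisection.

    Pass a :class:`Demography` (its F_fn is used) or explicit callables;
    with (r, gamma, mu) given, solves r(m)γ(m) − μ(m) = 0.
    """
    if dem is not None:
        fn = lambda m: float(dem.F_fn(np.zeros(1), m))
    elif F is not None:
        fn = lambda m: float(F(m))
    else:
        r = r if r is not None else (lambda m: 1.0)
        fn = lambda m: float(r(m)) * float(gamma(m)) - float(mu(m))
    ms = np.linspace(m_min, m_max, 4001)
    vals = np.array([fn(m) for m in ms])
    roots = []
    for i in range(len(ms) - 1):
        if vals[i] == 0.0:
            roots.append(ms[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(fn, ms[i], ms[i + 1], xtol=1e-12))
    # keep roots with F' < 0 (finite difference)
    h = 1e-6
    stable = [m for m in roots if fn(m + h) - fn(m - h) < 0]
    if not stable:
        raise NoEquilibriumError(
            f"no root of F with F' < 0 on ({m_min}, {m_max}]")
    return float(stable[0])


def _rho_tilde(k: KernelSpec, u, convention: str) -> np.ndarray:
    hat = kernel_fourier(k, u)
    return hat if convention == "paper" else 2.0 * math.pi * hat


def growth_rate(u, spec: DispersionSpec, convention: str = "dynamical"):
    """Linear growth rate λ(u) of the spatial mode e^{iux}.

    ``convention="dynamical"`` (default) uses the normalized kernel
    transform ρ̃ (ρ̃(0) = 1), which is the factor produced by the
    convolution theorem and therefore matches the mode dynamics of the
    nonlocal solver; ``"paper"`` keeps a 1/(2π) prefactor on the kernel
    factors as in the conventional display of the relation.  The two differ
    by positive constants on individual terms, so the *sign* structure in u
    (hence which bands are unstable for given σ²/ε²) differs only through
    the relative weight of the diffusive term; all package analyses use the
    dynamical convention.
    """
    u = np.asarray(u, dtype=float)
    rg_hat = _rho_tilde(spec.kernel_gamma, u, convention)
    rF_hat = _rho_tilde(spec.kernel_F, u, convention)
    lam = (-(u ** 2) * spec.sigma2 * spec.phi0 * spec.r0 * spec.gamma0p * rg_hat
           - (u ** 2) * spec.sigma2 * spec.r0 * spec.gamma0
           + spec.phi0 * spec.F0p * rF_hat)
    return lam


def unstable_band(spec: DispersionSpec, u_grid,
                  convention: str = "dynamical") -> DispersionResult:
    """Evaluate λ on a grid and bracket the sign changes by bisection."""
    u = np.asarray(u_grid, dtype=float)
    if np.any(u <= 0) or np.any(np.diff(u) <= 0):
        raise ValueError("u_grid must be positive and increasing")
    lam = growth_rate(u, spec, convention)
    f = lambda q: float(growth_rate(q, spec, convention))
    intervals = []
    start = None
    for i in range(len(u) - 1):
        if lam[i] <= 0 < lam[i + 1]:
            start = brentq(f, u[i], u[i + 1], xtol=1e-10)
        elif lam[i] > 0 >= lam[i + 1]:
            lo = start if start is not None else u[0]
            intervals.append((lo, brentq(f, u[i], u[i + 1], xtol=1e-10)))
            start = None
    if start is not None:
        intervals.append((start, float(u[-1])))
    if np.any(lam > 0):
        u_star = float(u[np.argmax(lam)])
    else:
        u_star = None
    return DispersionResult(u, lam, intervals, u_star)


def predicted_vs_observed_wavelength(spec: DispersionSpec, dem: Demography,
                                     disp, L: float, dx: float,
                                     rng: np.random.Generator,
                                     T: float = 60.0, dt: float = 5e-3,
                                     amplitude: float = 1e-3,
                                     u_grid=None):
    """Linear-theory wavelength 2π/u* versus the saturated nonlocal pattern.

    Runs :func:`lrpop.pde.solve_nonlocal` from φ0 plus small white noise and
    reads the dominant wavelength off the spatial power spectrum of the
    final state.  Returns (predicted, observed); observed is None when the
    perturbation decays (stable spec).
    """
    from .fields import DensityField
    from .pde import solve_nonlocal

    if u_grid is None:
        u_grid = np.linspace(0.05, 6.0 * math.pi / spec.kernel_F.scale, 2000)
    band = unstable_band(spec, u_grid)
    predicted = (2.0 * math.pi / band.u_star) if band.u_star else None
    G = int(round(L / dx))
    phi0 = DensityField(spec.phi0 + amplitude * rng.standard_normal(G),
                        dx=dx, boundary="periodic")
    traj = solve_nonlocal(phi0, dem, disp, T=T, dt=dt, record_every=T)
    v = traj.final.values
    dev = v - v.mean()
    if np.max(np.abs(dev)) < 5.0 * amplitude:
        return predicted, None
    power = np.abs(np.fft.rfft(dev)) ** 2
    freqs = np.fft.rfftfreq(G, d=dx)       # cycles per unit length
    k = int(np.argmax(power[1:])) + 1
    observed = 1.0 / freqs[k]
    return predicted, observed
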
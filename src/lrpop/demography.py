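"""Model ingredients: smoothing kernels, density-dependent demographic rates,
and Gaussian dispersal.

Population dynamics are controlled by three density-dependent quantities:
the birth rate γ(x, m), the establishment probability r(x, m) ∈ [0, 1] of a
freshly dispersed juvenile, and a function F(x, m) that parameterizes the
death rate through its deviation from rγ,

    μ_θ(x, m) = r(x, m_r) γ(x, m_γ) − F(x, m_F)/θ ,

so that θ(rγ − μ_θ) = F exactly.  Each rate reads the local density m
through its own smoothing kernel (ρ_γ, ρ_r, ρ_F); the local density is the
convolution of the scaled atomic measure η = X/N with that kernel.

Rate functions are drawn from a closed registry of named parametric forms
so configurations serialize, and so nonnegativity of μ_θ can be validated
up front on a declared admissible density range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .domain import Domain
from .population import PointPopulation

__all__ = [
    "KernelSpec",
    "RateFunction",
    "rate_function",
    "Demography",
    "DispersalSpec",
    "NonpositiveDeathRateError",
    "kernel_value",
    "kernel_fourier",
    "local_density",
    "death_rate",
    "sample_dispersal",
    "logistic_demography",
    "pme_demography",
    "neutral_demography",
]

TWO_PI = 2.0 * math.pi


class NonpositiveDeathRateError(ValueError):
    """The per-capita death rate μ_θ came out negative."""


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class KernelSpec:
    """A nonnegative, symmetric smoothing kernel integrating to one.

    family
        ``"gaussian"`` (scale = standard deviation) or ``"tophat"``
        (scale = half-width ε, 1D only).
    """

    family: str = "gaussian"
    scale: float = 1.0
    dim: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "tophat"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("kernel scale must be positive")
        if self.dim not in (1, 2):
            raise ValueError("kernel dim must be 1 or 2")
        if self.family == "tophat" and self.dim != 1:
            raise ValueError("tophat kernel implemented for dim=1 only")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return kernel_value(self, x)


def kernel_value(k: KernelSpec, x: np.ndarray) -> np.ndarray:
    """Pointwise kernel density ρ(x).

    ``x`` may be a scalar (1D), a d-vector, or an (..., d) array of
    displacement vectors; returns the matching array of densities.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        x = x.reshape(1)
    if x.shape[-1] != k.dim and k.dim == 1:
        x = x[..., None]
    sq = np.sum(x * x, axis=-1)
    if k.family == "gaussian":
        s2 = k.scale ** 2
        return np.exp(-sq / (2.0 * s2)) / (TWO_PI * s2) ** (k.dim / 2.0)
    # tophat, d=1
    return np.where(sq <= k.scale ** 2, 1.0 / (2.0 * k.scale), 0.0)


def kernel_cell_average(k: KernelSpec, xs: np.ndarray, dx: float) -> np.ndarray:
    """Average of ρ over grid cells [x − dx/2, x + dx/2] (1D).

    Exact via the kernel CDF; point-sampling a discontinuous kernel (the
    top-hat) on a grid shifts its effective support by O(dx), which visibly
    distorts its Fourier transform near the sinc zeros — cell averaging
    removes that bias.
    """
    if k.dim != 1:
        raise ValueError("kernel_cell_average requires dim=1")
    xs = np.asarray(xs, dtype=float).reshape(-1)
    hi, lo = xs + dx / 2.0, xs - dx / 2.0
    if k.family == "gaussian":
        from scipy.special import erf
        s = k.scale * math.sqrt(2.0)
        cdf = lambda q: 0.5 * (1.0 + erf(q / s))
    else:
        e = k.scale
        cdf = lambda q: np.clip((q + e) / (2.0 * e), 0.0, 1.0)
    return (cdf(hi) - cdf(lo)) / dx


def kernel_fourier(k: KernelSpec, u: np.ndarray) -> np.ndarray:
    """Fourier transform ρ̂(u) = ∫ e^{iux} ρ(x) dx / (2π)  (1D).

    Under this convention ρ̂(0) = 1/(2π) for any normalized kernel.
    Gaussian: exp(−scale²u²/2)/(2π).  Tophat: sin(εu)/(2πεu), which is
    negative for u ∈ (π/ε, 2π/ε) — the sign change that drives clumping.
    """
    if k.dim != 1:
        raise ValueError("kernel_fourier requires dim=1")
    u = np.asarray(u, dtype=float)
    if k.family == "gaussian":
        return np.exp(-(k.scale ** 2) * u ** 2 / 2.0) / TWO_PI
    eu = k.scale * u
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(eu == 0.0, 1.0 / TWO_PI, np.sin(eu) / (TWO_PI * eu))
    return val


# ---------------------------------------------------------------------------
# rate-function registry


@dataclass(frozen=True)
class RateFunction:
    """A named parametric rate function of (location x, local density m).

    The registry is closed: ``name`` is one of the forms below, so configs
    round-trip through plain text.  ``tabulated`` interpolates a table in m.
    """

    name: str
    params: tuple = ()

    def __call__(self, x: np.ndarray, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        p = self.params
        if self.name == "constant":
            return np.full_like(m, p[0])
        if self.name == "logistic_F":
            return 1.0 - m
        if self.name == "bistable_F":
            s = p[0]
            return (1.0 - m) * (2.0 * m - 1.0 + s)
        if self.name == "linear_gamma":
            cap = p[0] if p else 20.0
            return np.minimum(m, cap)
        if self.name == "saturating_gamma":
            a, b = p
            return a / (b + m)
        if self.name == "tabulated":
            grid, vals = p
            return np.interp(m, np.asarray(grid), np.asarray(vals))
        if self.name == "tabulated_x":
            # tabulated in the first spatial coordinate, constant in density
            grid, vals = p
            x1 = np.atleast_2d(np.asarray(x, dtype=float))[..., 0]
            out = np.interp(x1, np.asarray(grid), np.asarray(vals))
            return np.broadcast_to(out, np.broadcast_shapes(out.shape, m.shape)).copy() \
                if m.shape else out
        raise ValueError(f"unknown rate function {self.name!r}")

    @property
    def cap(self) -> float:
        """Declared upper bound over the admissible density range."""
        if self.name == "constant":
            return float(self.params[0])
        if self.name == "linear_gamma":
            return float(self.params[0]) if self.params else 20.0
        if self.name == "saturating_gamma":
            a, b = self.params
            return a / b
        if self.name in ("tabulated", "tabulated_x"):
            return float(np.max(self.params[1]))
        return math.inf


def rate_function(name: str, *params) -> RateFunction:
    """Construct a registered rate function, e.g. ``rate_function("constant", 1.0)``."""
    if name in ("tabulated", "tabulated_x"):
        grid, vals = params
        params = (tuple(np.asarray(grid, float)), tuple(np.asarray(vals, float)))
    return RateFunction(name, tuple(params))


# ---------------------------------------------------------------------------
# demography


@dataclass
class Demography:
    """The triple (γ, r, F) with the scaling parameters θ and N.

    ``kernels`` maps ``"gamma"``, ``"r"``, ``"F"`` to :class:`KernelSpec`.
    ``m_range`` is the admissible local-density range on which μ_θ ≥ 0 is
    validated at construction (the model assumption that death rates are
    nonnegative is enforced, never silently clipped).
    """

    gamma_fn: RateFunction
    r_fn: RateFunction
    F_fn: RateFunction
    theta: float
    N: float
    kernels: dict[str, KernelSpec] = field(default_factory=dict)
    m_range: tuple[float, float] = (0.0, 10.0)
    validate: bool = True

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.N <= 0:
            raise ValueError("theta and N must be positive")
        for key in ("gamma", "r", "F"):
            self.kernels.setdefault(key, KernelSpec("gaussian", 1.0, 1))
        if self.validate:
            self._validate_rates()

    @property
    def alpha(self) -> float:
        """θ/N: zero-ish for deterministic limits, order one for superprocess ones."""
        return self.theta / self.N

    def _validate_rates(self, n_grid: int = 201) -> None:
        m = np.linspace(self.m_range[0], self.m_range[1], n_grid)
        x = np.zeros_like(m)
        r = self.r_fn(x, m)
        if np.any(r < -1e-12) or np.any(r > 1.0 + 1e-12):
            raise ValueError("establishment probability r must lie in [0, 1]")
        g = self.gamma_fn(x, m)
        if np.any(g < -1e-12):
            raise ValueError("birth rate gamma must be nonnegative")
        if not np.isfinite(self.gamma_fn.cap):
            raise ValueError("gamma must declare a finite cap")
        mu = r * g - self.F_fn(x, m) / self.theta
        if np.any(mu < -1e-12):
            bad = m[np.argmin(mu)]
            raise NonpositiveDeathRateError(
                f"mu_theta < 0 at m={bad:.4g} on the declared density range "
                f"{self.m_range}; adjust theta or the admissible range")

    def mu_theta(self, x, m_r, m_gamma, m_F):
        """Death rate μ_θ = r(x,m_r)γ(x,m_γ) − F(x,m_F)/θ."""
        return death_rate(self, x, m_r, m_gamma, m_F)


def death_rate(dem: Demography, x, m_r, m_gamma, m_F):
    """Per-capita death rate; raises if any value is negative.

    The three density arguments are the kernel-smoothed densities at x read
    through ρ_r, ρ_γ and ρ_F respectively.
    """
    x = np.asarray(x, dtype=float)
    mu = (np.asarray(dem.r_fn(x, m_r)) * np.asarray(dem.gamma_fn(x, m_gamma))
          - np.asarray(dem.F_fn(x, m_F)) / dem.theta)
    if np.any(mu < 0):
        i = int(np.argmin(np.atleast_1d(mu)))
        mr = np.atleast_1d(np.asarray(m_r, float))
        raise NonpositiveDeathRateError(
            f"negative death rate mu_theta={np.atleast_1d(mu)[i]:.4g} at "
            f"x={np.atleast_2d(x)[min(i, np.atleast_2d(x).shape[0]-1)]}, "
            f"m_r={mr[min(i, mr.size-1)]:.4g}")
    return mu if mu.shape else float(mu)


# ---------------------------------------------------------------------------
# local density


def local_density(pop: PointPopulation, k: KernelSpec, x) -> np.ndarray:
    """Kernel-smoothed density (ρ * η)(x) = (1/N) Σ_i ρ(x − x_i).

    ``x`` may be a single point or an (m, d) array of evaluation points.
    Displacements use the minimal image on periodic domains.  An atom at x
    contributes its own mass ρ(0)/N (the convolution has no self-exclusion).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    scalar = x.shape[0] == 1
    if pop.n == 0:
        out = np.zeros(x.shape[0])
        return float(out[0]) if scalar else out
    diff = pop.domain.displacement(x[:, None, :] - pop.positions[None, :, :])
    vals = kernel_value(k, diff).sum(axis=1) / pop.N
    return float(vals[0]) if scalar else vals


# ---------------------------------------------------------------------------
# dispersal


@dataclass
class DispersalSpec:
    """Gaussian dispersal: a juvenile lands at x + b(x)/θ + K(x)z/√θ.

    ``mean`` is the unscaled drift vector b (or a callable b(x)); ``cov``
    the unscaled covariance matrix C (or callable), with C = σ²I expressible
    through ``sigma2``.  The generator of the θ→∞ diffusion limit is
    𝓑 = ½ΣC_ij∂i∂j + Σb_i∂i.
    """

    theta: float
    dim: int = 1
    mean: object = None       # vector or callable x -> vector
    cov: object = None        # matrix or callable x -> matrix
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = np.zeros(self.dim)
        if self.cov is None:
            s2 = 1.0 if self.sigma2 is None else float(self.sigma2)
            self.cov = s2 * np.eye(self.dim)
        elif self.sigma2 is None and not callable(self.cov):
            C = np.asarray(self.cov, float)
            if np.allclose(C, C[0, 0] * np.eye(self.dim)):
                self.sigma2 = float(C[0, 0])

    def b(self, x) -> np.ndarray:
        if callable(self.mean):
            return np.asarray(self.mean(x), float)
        return np.broadcast_to(np.asarray(self.mean, float),
                               np.atleast_2d(x).shape[:-1] + (self.dim,))

    def C(self, x) -> np.ndarray:
        if callable(self.cov):
            C = np.asarray(self.cov(x), float)
        else:
            C = np.asarray(self.cov, float)
        if not np.all(np.linalg.eigvalsh(np.atleast_2d(C)) > 0):
            raise np.linalg.LinAlgError("dispersal covariance is not SPD")
        return C

    def cholesky(self, x) -> np.ndarray:
        return np.linalg.cholesky(np.atleast_2d(self.C(x)))


def sample_dispersal(disp: DispersalSpec, x, rng: np.random.Generator,
                     domain: Domain | None = None, size: int | None = None):
    """Draw offspring landing site(s) y = x + b(x)/θ + K(x)z/√θ.

    With ``size`` set, draws that many independent displacements from the
    same parent location.  Positions are wrapped into periodic domains.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    d = x.size
    n = 1 if size is None else size
    K = disp.cholesky(x)
    z = rng.standard_normal((n, d))
    b = np.asarray(disp.b(x), float).reshape(-1)[:d]
    y = x[None, :] + b[None, :] / disp.theta + (z @ K.T) / math.sqrt(disp.theta)
    if domain is not None:
        y = domain.wrap(y)
    return y[0] if size is None else y


# ---------------------------------------------------------------------------
# quadrature against q_theta (used by the lookdown level coefficients)

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gauss_hermite_expectation(f, disp: DispersalSpec, x, M: int = 20):
    """E[f(Y)] for Y ~ q_θ(x, ·) by M-point Gauss–Hermite quadrature per axis."""
    x = np.asarray(x, dtype=float).reshape(-1)
    d = x.size
    if M not in _GH_CACHE:
        _GH_CACHE[M] = hermegauss(M)
    nodes, weights = _GH_CACHE[M]
    weights = weights / weights.sum()
    K = disp.cholesky(x) / math.sqrt(disp.theta)
    b = np.asarray(disp.b(x), float).reshape(-1)[:d]
    if d == 1:
        ys = x[None, :] + b[None, :] / disp.theta + nodes[:, None] * K[0, 0]
        return float(np.sum(weights * np.asarray(f(ys)).reshape(-1)))
    zz = np.stack(np.meshgrid(nodes, nodes, indexing="ij"), axis=-1).reshape(-1, 2)
    ww = (weights[:, None] * weights[None, :]).reshape(-1)
    ys = x[None, :] + b[None, :] / disp.theta + zz @ K.T
    return float(np.sum(ww * np.asarray(f(ys)).reshape(-1)))


# ---------------------------------------------------------------------------
# presets


def logistic_demography(theta: float, N: float, kernel_scale: float = 1.0,
                        dim: int = 1) -> Demography:
    """r≡1, γ≡1, F = 1−m: the Fisher-KPP-like parameterization."""
    ks = {k: KernelSpec("gaussian", kernel_scale, dim) for k in ("gamma", "r", "F")}
    return Demography(rate_function("constant", 1.0), rate_function("constant", 1.0),
                      rate_function("logistic_F"), theta, N, ks)


def pme_demography(theta: float, N: float, kernel_scale: float = 1.0,
                   dim: int = 1, gamma_cap: float = 20.0) -> Demography:
    """r≡1, γ=m (capped), F = 1−m: density-dependent motility.

    Here μ_θ = m(1+1/θ) − 1/θ, which is nonnegative only for
    m ≥ 1/(θ+1); that is the declared lower edge of the admissible range.
    The scaling limit is the porous-medium equation with logistic growth.
    """
    ks = {k: KernelSpec("gaussian", kernel_scale, dim) for k in ("gamma", "r", "F")}
    return Demography(rate_function("linear_gamma", gamma_cap),
                      rate_function("constant", 1.0),
                      rate_function("logistic_F"), theta, N, ks,
                      m_range=(1.0 / (theta + 1.0), 10.0))


def neutral_demography(theta: float, N: float, kernel_scale: float = 1.0,
                       dim: int = 1) -> Demography:
    """r≡1, γ≡1, F≡0 (so μ_θ = 1): critical branching, no regulation."""
    ks = {k: KernelSpec("gaussian", kernel_scale, dim) for k in ("gamma", "r", "F")}
    return Demography(rate_function("constant", 1.0), rate_function("constant", 1.0),
                      rate_function("constant", 0.0), theta, N, ks)
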
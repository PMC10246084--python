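"""Lookdown representation of the population process.

Each individual carries a "level": in the finite-N model, levels are
conditionally i.i.d. Uniform[0, N] given the spatial configuration, and in
the infinite-density limit they form a conditionally Poisson configuration
on [0, ∞).  Levels make sampling trivial — the k individuals with the
lowest levels in a region are a uniform sample of size k — and they let
lines of descent, and hence genealogies, survive the passage to the
scaling limit.

Dynamics (finite-N mode):

* an individual at x with level u proposes a birth at rate 2θ(1 − u/N)γ(x, η);
  the juvenile disperses by q_θ and establishes with probability r(y, η);
* on establishment, a new level u₁ ~ Uniform[u, N] is created and handed to
  parent or offspring with probability ½ each (the coin κ); the line of
  descent keeps the *old* level, and a fresh Ulam–Harris label is given to
  whichever individual received the new level;
* between events the level of an individual at x solves
  u̇ = c_θ(x,η) u² − b_θ(x,η) u, and individuals whose levels cross N die.

In limit mode (θ/N → α) new lines of descent appear at rate 2αγr per unit
level above the parent's level (truncated at a tracking ceiling u_max),
spatial motion of a line is the diffusion dX = β dt + J dW with
β = rγ(b + C∇log r) and JJᵀ = rγC, and levels follow
u̇ = αγr u² − (γ𝓑r + F)u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import (Demography, DispersalSpec, gauss_hermite_expectation,
                         local_density, sample_dispersal)
from .domain import Domain
from .population import PointPopulation

__all__ = [
    "LookdownState", "EventRecord", "level_coeffs", "evolve_level",
    "level_crossing_time", "lookdown_run", "project", "sample_k_lowest",
    "trace_lineage", "export_genealogy", "InsufficientSampleError",
]


class InsufficientSampleError(ValueError):
    """Fewer alive individuals in the region than requested."""


Label = tuple[int, ...]


def format_label(label: Label) -> str:
    return ".".join(str(i) for i in label)


@dataclass
class EventRecord:
    time: float
    kind: str                  # "birth" | "death"
    parent_label: Label | None
    child_label: Label | None
    x_parent: np.ndarray | None
    x_child: np.ndarray | None
    u_new: float | None
    kappa: int | None


@dataclass
class LookdownState:
    """Alive individuals of the levelled process plus the append-only log."""

    positions: np.ndarray            # (n, d)
    levels: np.ndarray               # (n,)
    labels: list[Label]
    domain: Domain
    mode: str = "finite_N"           # "finite_N" | "limit"
    N: float | None = None           # finite_N level cap
    alpha: float | None = None       # limit-mode branching rate scale
    u_max: float | None = None       # limit-mode tracking ceiling
    time: float = 0.0
    event_log: list[EventRecord] = field(default_factory=list)
    _label_counter: dict[Label, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, self.domain.dim)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.mode == "finite_N" and self.N is None:
            raise ValueError("finite_N mode requires N")
        if self.mode == "limit" and (self.alpha is None or self.u_max is None):
            raise ValueError("limit mode requires alpha and u_max")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def cap(self) -> float:
        return self.N if self.mode == "finite_N" else self.u_max

    def new_child_label(self, parent: Label) -> Label:
        j = self._label_counter.get(parent, 0) + 1
        self._label_counter[parent] = j
        return parent + (j,)

    @classmethod
    def from_population(cls, pop: PointPopulation, rng: np.random.Generator,
                        mode: str = "finite_N", alpha: float | None = None,
                        u_max: float | None = None) -> "LookdownState":
        """Attach levels: Uniform[0,N] (finite_N) or Uniform[0,u_max] (limit)."""
        n = pop.n
        if mode == "finite_N":
            levels = rng.uniform(0.0, pop.N, size=n)
            return cls(pop.positions.copy(), levels, [(i + 1,) for i in range(n)],
                       pop.domain, mode="finite_N", N=pop.N, time=pop.time)
        levels = rng.uniform(0.0, u_max, size=n)
        return cls(pop.positions.copy(), levels, [(i + 1,) for i in range(n)],
                   pop.domain, mode="limit", alpha=alpha, u_max=u_max,
                   time=pop.time)


# ---------------------------------------------------------------------------
# level dynamics


def level_coeffs(x, pop: PointPopulation, dem: Demography, disp: DispersalSpec,
                 M: int = 20) -> tuple[float, float]:
    """(b_level, c_level) of the level ODE u̇ = c u² − b u at location x.

    c = (θ/N) γ(x,η) ∫ r(y,η) q_θ(x,dy) — the local rate of production of
    established offspring; b = θγ(x,η)∫(r(y,η)−r(x,η))q_θ(x,dy) + F(x,η) —
    the local net growth felt by levels.  The q_θ integrals use M-point
    Gauss–Hermite quadrature per axis.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    theta, N = dem.theta, dem.N
    mg = local_density(pop, dem.kernels["gamma"], x)
    mf = local_density(pop, dem.kernels["F"], x)
    g = float(np.atleast_1d(dem.gamma_fn(x, mg))[0])
    F = float(np.atleast_1d(dem.F_fn(x, mf))[0])
    if dem.r_fn.name == "constant":
        r0 = float(dem.r_fn.params[0])
        return F, (theta / N) * g * r0

    def r_at(ys):
        m = local_density(pop, dem.kernels["r"], ys)
        return np.asarray(dem.r_fn(ys, m))

    r_int = gauss_hermite_expectation(r_at, disp, x, M=M)
    mr = local_density(pop, dem.kernels["r"], x)
    r_x = float(np.atleast_1d(dem.r_fn(x, mr))[0])
    b = theta * g * (r_int - r_x) + F
    c = (theta / N) * g * r_int
    return b, c


def evolve_level(u0, b, c, dt):
    """Closed-form solution of u̇ = c u² − b u with frozen coefficients.

    Works elementwise on arrays.  Returns (u(dt), escape_time) where
    escape_time is the time at which the level reaches +∞ (NaN where the
    level stays finite; u is +inf there).  With v = 1/u the ODE is linear,
    v̇ = b v − c, so v(t) = c/b + (v0 − c/b)e^{bt} (b ≠ 0) or v0 − ct (b = 0).
    """
    u0 = np.asarray(u0, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), u0.shape).copy()
    c = np.broadcast_to(np.asarray(c, dtype=float), u0.shape).copy()
    if np.any(u0 <= 0):
        raise ValueError("levels must be positive")
    v0 = 1.0 / u0
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio = np.where(b != 0.0, c / np.where(b != 0.0, b, 1.0), 0.0)
        vt = np.where(b != 0.0,
                      ratio + (v0 - ratio) * np.exp(b * dt),
                      v0 - c * dt)
        # escape: v hits 0 at t* in (0, dt]
        t_esc = np.full(u0.shape, np.nan)
        nz = (b != 0.0) & (v0 - ratio != 0.0)
        arg = np.where(nz, ratio / np.where(nz, ratio - v0, 1.0), np.nan)
        t_b = np.where(nz & (arg > 0), np.log(arg) / b, np.nan)
        t_0 = np.where((b == 0.0) & (c > 0), v0 / c, np.nan)
        t_cand = np.where(b != 0.0, t_b, t_0)
        esc = np.isfinite(t_cand) & (t_cand > 0) & (t_cand <= dt)
        t_esc = np.where(esc, t_cand, np.nan)
        ut = np.where(esc | (vt <= 0), np.inf, 1.0 / np.where(vt > 0, vt, 1.0))
    if ut.shape == ():
        return float(ut), (float(t_esc) if np.isfinite(t_esc) else None)
    return ut, t_esc


def level_crossing_time(u0, b, c, cap, dt):
    """Elementwise time in (0, dt] at which the level crosses ``cap`` (NaN if not).

    Solves v(t) = 1/cap for the linear ODE of :func:`evolve_level`.
    """
    u0 = np.asarray(u0, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), u0.shape)
    c = np.broadcast_to(np.asarray(c, dtype=float), u0.shape)
    v0 = 1.0 / u0
    vc = 1.0 / cap
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio = np.where(b != 0.0, c / np.where(b != 0.0, b, 1.0), 0.0)
        argn = vc - ratio
        argd = v0 - ratio
        ok = (b != 0.0) & (argn / np.where(argd != 0, argd, np.nan) > 0)
        t_b = np.where(ok, np.log(np.where(ok, argn / argd, 1.0)) /
                       np.where(b != 0, b, 1.0), np.nan)
        t_0 = np.where((b == 0.0) & (c > 0), (v0 - vc) / c, np.nan)
        t = np.where(b != 0.0, t_b, t_0)
        t = np.where(np.isfinite(t) & (t > 0) & (t <= dt), t, np.nan)
    return t


# ---------------------------------------------------------------------------
# forward run


def _population_view(state: LookdownState) -> PointPopulation:
    N_eff = state.N if state.mode == "finite_N" else state.u_max
    return PointPopulation(state.positions, N_eff, state.domain,
                           time=state.time)


def _finite_coeffs_all(state: LookdownState, dem: Demography,
                       disp: DispersalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (b_i, c_i) for every alive individual (finite_N)."""
    pop = _population_view(state)
    x = state.positions
    mg = np.atleast_1d(local_density(pop, dem.kernels["gamma"], x))
    mf = np.atleast_1d(local_density(pop, dem.kernels["F"], x))
    g = np.asarray(dem.gamma_fn(x, mg), dtype=float)
    F = np.asarray(dem.F_fn(x, mf), dtype=float)
    if dem.r_fn.name == "constant":
        r0 = float(dem.r_fn.params[0])
        return F, (dem.theta / dem.N) * g * r0
    b = np.empty(state.n)
    c = np.empty(state.n)
    for i in range(state.n):
        b[i], c[i] = level_coeffs(x[i], pop, dem, disp)
    return b, c


def lookdown_run(state0: LookdownState, dem: Demography, disp: DispersalSpec,
                 T: float, rng: np.random.Generator,
                 dt_max: float | None = None,
                 n_max: int | None = None) -> LookdownState:
    """Run the lookdown process to scaled time T (in place on a copy).

    Between events, level-ODE coefficients are frozen at their values at the
    last refresh (exact closed form per piece); ``dt_max`` (default 0.01/θ
    scaled time) forces refreshes in event-sparse phases.  Birth proposals
    use thinning at the global bound 2θγ_max.
    """
    st = LookdownState(state0.positions.copy(), state0.levels.copy(),
                       list(state0.labels), state0.domain, mode=state0.mode,
                       N=state0.N, alpha=state0.alpha, u_max=state0.u_max,
                       time=state0.time,
                       event_log=list(state0.event_log),
                       _label_counter=dict(state0._label_counter))
    if st.mode == "finite_N":
        _run_finite(st, dem, disp, T, rng, dt_max, n_max)
    else:
        _run_limit(st, dem, disp, T, rng, dt_max, n_max)
    return st


def _remove(st: LookdownState, idx: np.ndarray, times: np.ndarray) -> None:
    for i in sorted(np.atleast_1d(idx).tolist(), reverse=True):
        st.event_log.append(EventRecord(
            float(times[i]) if np.ndim(times) else float(times),
            "death", st.labels[i], None, st.positions[i].copy(), None,
            None, None))
        st.positions = np.delete(st.positions, i, axis=0)
        st.levels = np.delete(st.levels, i)
        del st.labels[i]


def _advance_levels_finite(st, dem, disp, dt):
    """Evolve all levels over dt with frozen coefficients; remove escapes."""
    if st.n == 0:
        return
    b, c = _finite_coeffs_all(st, dem, disp)
    t_cross = level_crossing_time(st.levels, b, c, st.cap, dt)
    u_new, _ = evolve_level(st.levels, b, c, dt)
    dead = np.where(np.isfinite(t_cross))[0]
    alive_levels = np.where(np.isfinite(t_cross), st.levels, u_new)
    st.levels = alive_levels
    if dead.size:
        _remove(st, dead, st.time + t_cross)
    st.levels = np.minimum(st.levels, st.cap)  # numerical guard


def _run_finite(st, dem, disp, T, rng, dt_max, n_max):
    theta, N = dem.theta, dem.N
    if dt_max is None:
        dt_max = 0.01 / theta
    if n_max is None:
        n_max = max(1000, int(100 * N * st.domain.volume))
    gamma_max = dem.gamma_fn.cap
    while st.time < T and st.n > 0:
        if st.n > n_max:
            raise RuntimeError(f"lookdown population exceeded n_max={n_max}")
        n_pre = st.n
        R = 2.0 * theta * gamma_max * n_pre
        dt_event = rng.exponential(1.0 / R) if R > 0 else np.inf
        dt = min(dt_event, dt_max, T - st.time)
        _advance_levels_finite(st, dem, disp, dt)
        st.time += dt
        if dt < dt_event or st.n == 0 or st.time >= T:
            continue
        # proposal: uniform individual, thinned by (1 - u/N) gamma / gamma_max;
        # the n/n_pre factor corrects the bound for deaths that occurred
        # while levels were advanced across this interval
        i = int(rng.integers(st.n))
        pop = _population_view(st)
        mg = local_density(pop, dem.kernels["gamma"], st.positions[i])
        g = float(dem.gamma_fn(st.positions[i], mg))
        accept = ((1.0 - st.levels[i] / N) * g / gamma_max) * (st.n / n_pre)
        if rng.random() >= accept:
            continue
        y = sample_dispersal(disp, st.positions[i], rng, domain=st.domain)
        mr = local_density(pop, dem.kernels["r"], y)
        if rng.random() >= float(np.atleast_1d(dem.r_fn(y, mr))[0]):
            continue
        u1 = rng.uniform(st.levels[i], N)
        kappa = int(rng.integers(2))
        parent_label = st.labels[i]
        child_label = st.new_child_label(parent_label)
        x_parent = st.positions[i].copy()
        if kappa == 0:
            # offspring takes the new level and the new label
            new_pos, old_pos = y, x_parent
        else:
            # parent individual takes the new level/label; the line of
            # descent (old label, old level) continues through the offspring
            new_pos, old_pos = x_parent, y
        st.positions[i] = old_pos
        st.positions = np.vstack([st.positions, new_pos[None, :]])
        st.levels = np.append(st.levels, u1)
        st.labels.append(child_label)
        st.event_log.append(EventRecord(st.time, "birth", parent_label,
                                        child_label, x_parent, np.asarray(y),
                                        float(u1), kappa))


def _limit_fields(st, dem, disp, h=1e-4):
    """Per-individual (gamma, r, F, Br, grad_log_r) in limit mode."""
    pop = _population_view(st)
    x = st.positions
    mg = np.atleast_1d(local_density(pop, dem.kernels["gamma"], x))
    mf = np.atleast_1d(local_density(pop, dem.kernels["F"], x))
    g = np.asarray(dem.gamma_fn(x, mg), dtype=float)
    F = np.asarray(dem.F_fn(x, mf), dtype=float)
    if dem.r_fn.name == "constant":
        r = np.full(st.n, float(dem.r_fn.params[0]))
        Br = np.zeros(st.n)
        glr = np.zeros_like(x)
        return g, r, F, Br, glr

    def r_field(pts):
        m = np.atleast_1d(local_density(pop, dem.kernels["r"], pts))
        return np.asarray(dem.r_fn(pts, m), dtype=float)

    r = r_field(x)
    d = x.shape[1]
    grad = np.zeros_like(x)
    lap = np.zeros(st.n)
    for j in range(d):
        e = np.zeros(d); e[j] = h
        rp, rm = r_field(x + e), r_field(x - e)
        grad[:, j] = (rp - rm) / (2 * h)
        lap += (rp - 2 * r + rm) / h ** 2
    C = np.atleast_2d(disp.C(x[0]))
    bvec = np.asarray(disp.b(x[0]), float).reshape(-1)[:d]
    if not np.allclose(C, C[0, 0] * np.eye(d)):
        raise NotImplementedError("limit mode assumes isotropic C")
    Br = 0.5 * C[0, 0] * lap + grad @ bvec
    glr = grad / np.maximum(r[:, None], 1e-300)
    return g, r, F, Br, glr


def _run_limit(st, dem, disp, T, rng, dt_max, n_max):
    """Euler scheme for the limit-mode line-of-descent system."""
    alpha, u_max = st.alpha, st.u_max
    if dt_max is None:
        dt_max = 0.01
    if n_max is None:
        n_max = 100_000
    d = st.domain.dim
    C = np.atleast_2d(disp.C(np.zeros(d)))
    K = np.linalg.cholesky(C)
    bvec = np.asarray(disp.b(np.zeros(d)), float).reshape(-1)[:d]
    while st.time < T and st.n > 0:
        if st.n > n_max:
            raise RuntimeError(f"lookdown population exceeded n_max={n_max}")
        dt = min(dt_max, T - st.time)
        g, r, F, Br, glr = _limit_fields(st, dem, disp)
        rg = r * g
        # spatial diffusion: beta = rγ(b + C ∇log r), J Jᵀ = rγ C
        beta = rg[:, None] * (bvec[None, :] + glr @ C.T)
        noise = rng.standard_normal((st.n, d)) @ K.T
        st.positions = st.domain.wrap(
            st.positions + beta * dt + np.sqrt(np.maximum(rg, 0.0))[:, None]
            * noise * math.sqrt(dt))
        # levels: u̇ = αγr u² − (γ𝓑r + F) u
        b_lvl = g * Br + F
        c_lvl = alpha * rg
        t_cross = level_crossing_time(st.levels, b_lvl, c_lvl, u_max, dt)
        u_new, _ = evolve_level(st.levels, b_lvl, c_lvl, dt)
        dead = np.where(np.isfinite(t_cross))[0]
        st.levels = np.where(np.isfinite(t_cross), st.levels, u_new)
        if dead.size:
            _remove(st, dead, st.time + t_cross)
            g, r, F = g[np.isnan(t_cross)], r[np.isnan(t_cross)], F[np.isnan(t_cross)]
            rg = r * g
        st.time += dt
        if st.n == 0:
            break
        # new lines of descent: Poisson with intensity 2αγr per unit level
        # above the parent's level, tracked below u_max
        rate = 2.0 * alpha * rg * np.maximum(u_max - st.levels, 0.0)
        n_new = rng.poisson(rate * dt)
        for i in np.where(n_new > 0)[0]:
            for _ in range(int(n_new[i])):
                u1 = rng.uniform(st.levels[i], u_max)
                child = st.new_child_label(st.labels[i])
                st.positions = np.vstack([st.positions, st.positions[i][None, :]])
                st.levels = np.append(st.levels, u1)
                st.labels.append(child)
                st.event_log.append(EventRecord(
                    st.time, "birth", st.labels[i], child,
                    st.positions[i].copy(), st.positions[i].copy(),
                    float(u1), None))


# ---------------------------------------------------------------------------
# projection and sampling


def project(state: LookdownState) -> PointPopulation:
    """Forget levels: atoms at alive positions with mass 1/N (finite-N mode)
    or 1/u_max (limit mode, counting lines below the ceiling)."""
    N_eff = state.N if state.mode == "finite_N" else state.u_max
    return PointPopulation(state.positions.copy(), N_eff, state.domain,
                           time=state.time)


def sample_k_lowest(state: LookdownState, region, k: int):
    """The k alive individuals in the box ``region`` with smallest levels.

    ``region`` is a pair (lo, hi) of d-vectors.  By exchangeability of
    levels this is a uniform random sample of size k from the region.
    """
    lo, hi = (np.asarray(v, dtype=float).reshape(-1) for v in region)
    inside = np.all((state.positions >= lo) & (state.positions <= hi), axis=1)
    idx = np.where(inside)[0]
    if idx.size < k:
        raise InsufficientSampleError(
            f"region holds {idx.size} individuals, requested {k}")
    order = idx[np.argsort(state.levels[idx])][:k]
    return [(state.labels[i], state.positions[i].copy(), float(state.levels[i]))
            for i in order]


# ---------------------------------------------------------------------------
# lineage tracing and genealogy export


def _ancestry_segments(event_log: list[EventRecord], label: Label, T: float):
    """Walk the genealogical ancestry of the individual carrying ``label`` at T.

    Returns a list of (time, label, position-before-jump-or-None) steps in
    decreasing time: at each birth event on the ancestry, the lineage either
    stays put (the sampled line kept the parent role) or jumps to the
    parent's location (it received the offspring role: κ=0 if it is the new
    label, κ=1 if the old label followed the offspring).
    """
    steps = []
    cur = label
    for ev in reversed(event_log):
        if ev.time > T or ev.kind != "birth":
            continue
        if ev.child_label == cur:
            if ev.kappa == 0 or ev.kappa is None:
                # cur is the offspring individual: jump to the parent
                steps.append((ev.time, ev.parent_label, ev.x_parent))
            else:
                steps.append((ev.time, ev.parent_label, None))
            cur = ev.parent_label
        elif ev.parent_label == cur:
            if ev.kappa == 1:
                # the old label followed the offspring: jump back to parent
                steps.append((ev.time, cur, ev.x_parent))
            # kappa==0: cur stayed with the parent individual; no jump
    return steps


def trace_lineage(event_log: list[EventRecord], state: LookdownState,
                  label: Label, s: float, T: float | None = None):
    """Backward spatial path of the ancestral lineage of ``label`` over [T−s, T].

    Returns (backward_times, positions): backward time 0 is the sampling
    time T.  The lineage only moves at birth events (individuals do not
    move during their lifetime).
    """
    if T is None:
        T = state.time
    if label not in state.labels:
        raise KeyError(f"label {format_label(label)} not alive at T")
    x = state.positions[state.labels.index(label)].copy()
    times = [0.0]
    pos = [x.copy()]
    for (t_ev, _lab, jump_to) in _ancestry_segments(event_log, label, T):
        back = T - t_ev
        if back > s:
            break
        if jump_to is not None:
            times.append(back)
            pos.append(np.asarray(jump_to, dtype=float).copy())
    times.append(s)
    pos.append(pos[-1].copy())
    return np.asarray(times), np.vstack(pos)


def _ancestor_label_path(event_log, label: Label, T: float):
    """Piecewise-constant label of the ancestor individual: list of
    (t_from, t_to, label) covering [0, T], in decreasing time."""
    out = []
    t_hi = T
    cur = label
    for (t_ev, lab, _jump) in _ancestry_segments(event_log, label, T):
        if lab != cur:
            out.append((t_ev, t_hi, cur))
            t_hi = t_ev
            cur = lab
    out.append((0.0, t_hi, cur))
    return out


def _label_at(path, t: float) -> Label:
    for (a, b, lab) in path:
        if a <= t <= b:
            return lab
    return path[-1][2]


def export_genealogy(event_log: list[EventRecord], state: LookdownState,
                     sample: list[Label], T: float | None = None) -> str:
    """Newick forest for the sampled individuals, back to time 0.

    Branch lengths are in scaled time; leaf names are Ulam–Harris label
    strings; internal nodes sit at the birth events where sampled lineages
    diverge.  One Newick tree per founder, concatenated with newlines.
    """
    if T is None:
        T = state.time
    paths = {lab: _ancestor_label_path(event_log, lab, T) for lab in sample}
    k = len(sample)
    # pairwise divergence times: the highest event time below which the two
    # ancestor individuals still coincide (labels are evaluated just below
    # each segment boundary to avoid boundary ambiguity)
    eps = 1e-12 * max(T, 1.0)
    div = {}
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = paths[sample[i]], paths[sample[j]]
            bounds = sorted({a for (a, _b, _) in pi}
                            | {a for (a, _b, _) in pj} | {T})
            t_div = None
            for a in bounds:
                t = max(a - eps, 0.0)
                if _label_at(pi, t) == _label_at(pj, t):
                    t_div = a
            div[(i, j)] = t_div
    # single-linkage agglomeration at decreasing divergence times
    nodes = {i: (format_label(sample[i]), T) for i in range(k)}
    children: dict[int, list[int]] = {}
    times = {i: T for i in range(k)}
    parent_of = {}
    merges = sorted(((t, i, j) for (i, j), t in div.items() if t is not None),
                    key=lambda z: -z[0])
    cluster = {i: i for i in range(k)}
    next_id = k

    def find(i):
        while cluster[i] != i:
            cluster[i] = cluster[cluster[i]]
            i = cluster[i]
        return i

    for (t, i, j) in merges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        nid = next_id; next_id += 1
        children[nid] = [ri, rj]
        times[nid] = t
        cluster[ri] = cluster[rj] = nid
        cluster[nid] = nid
        parent_of[ri] = parent_of[rj] = nid

    roots = sorted({find(i) for i in range(k)})

    def newick(node) -> str:
        if node < k:
            return format_label(sample[node])
        parts = []
        for ch in children[node]:
            bl = times[ch] - times[node]
            parts.append(f"{newick(ch)}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"

    trees = []
    for root in roots:
        if root < k:
            trees.append(f"({format_label(sample[root])}:{T - 0.0:.10g});")
        else:
            trees.append(f"({newick(root)}:{times[root]:.10g});")
    return "\n".join(trees)
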
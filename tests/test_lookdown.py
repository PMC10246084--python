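"""Lookdown construction: levels, lines of descent, genealogies."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from lrpop import (Demography, DispersalSpec, Domain, KernelSpec,
                   logistic_demography, neutral_demography, poisson_uniform,
                   rate_function)
from lrpop.lookdown import (InsufficientSampleError, LookdownState,
                            evolve_level, export_genealogy, level_coeffs,
                            level_crossing_time, lookdown_run, project,
                            sample_k_lowest, trace_lineage)


# ---------------------------------------------------------------------------
# level ODE


def test_evolve_level_closed_forms():
    u, esc = evolve_level(np.array(2.0), 1.0, 0.0, math.log(2.0))
    assert u == pytest.approx(1.0)          # pure decay u0 e^{−bt}
    u, _ = evolve_level(np.array(2.0), 2.0, 1.0, 7.3)
    assert u == pytest.approx(2.0)          # fixed point u = b/c
    u, _ = evolve_level(np.array(2.0), 1.0, 1.0, math.log(4.0 / 3.0))
    assert u == pytest.approx(3.0, rel=1e-12)


def test_evolve_level_escape():
    # b=0, c>0: v = 1/u0 − ct hits 0 at t = 1/(c u0)
    u, t_esc = evolve_level(np.array(2.0), 0.0, 1.0, 1.0)
    assert np.isinf(u)
    assert t_esc == pytest.approx(0.5)
    # no escape when dt is short of the blow-up time
    u, t_esc = evolve_level(np.array(2.0), 0.0, 1.0, 0.25)
    assert np.isfinite(u) and t_esc is None
    assert u == pytest.approx(4.0)


def test_evolve_level_matches_runge_kutta():
    """Closed form vs an adaptive RK integrator over random coefficients,
    including escape detection."""
    rng = np.random.default_rng(7)
    checked_escape = 0
    for _ in range(300):
        u0 = rng.uniform(0.05, 30.0)
        b = rng.uniform(-4.0, 4.0)
        c = rng.uniform(0.0, 2.0)
        dt = rng.uniform(0.01, 2.0)
        u_cf, t_esc = evolve_level(np.array(u0), b, c, dt)
        blow = lambda t, v: v[0]          # escape in v = 1/u coordinates
        blow.terminal = True
        sol = solve_ivp(lambda t, v: [b * v[0] - c], (0.0, dt), [1.0 / u0],
                        rtol=1e-12, atol=1e-14, events=blow, max_step=dt / 8)
        if sol.t_events[0].size:
            assert np.isinf(u_cf)
            assert t_esc == pytest.approx(sol.t_events[0][0], abs=1e-8)
            checked_escape += 1
        else:
            assert np.isfinite(u_cf)
            assert 1.0 / u_cf == pytest.approx(sol.y[0, -1], abs=1e-8)
    assert checked_escape > 10


def test_level_crossing_time_against_closed_form():
    # u crosses cap exactly when the evolved level equals the cap
    u0, b, c, cap = 3.0, -0.5, 0.2, 10.0
    t = float(level_crossing_time(np.array(u0), b, c, cap, 10.0))
    u_at_t, _ = evolve_level(np.array(u0), b, c, t)
    assert u_at_t == pytest.approx(cap, rel=1e-10)


# ---------------------------------------------------------------------------
# level coefficients


def test_level_coeffs_constant_r_reduces_to_F(small_logistic, rng):
    dem, disp, dom = small_logistic
    pop = poisson_uniform(dem.N, 1.0, dom, rng)
    from lrpop import local_density
    x = np.array([0.5])
    b, c = level_coeffs(x, pop, dem, disp)
    mf = local_density(pop, dem.kernels["F"], x)
    assert b == pytest.approx(1.0 - mf)        # b = F(x, η) exactly
    assert c == pytest.approx(dem.theta / dem.N)


def test_level_coeffs_quadrature_vs_monte_carlo(rng):
    """Spatially varying establishment: Gauss–Hermite integral against a
    large Monte-Carlo sample of the dispersal kernel."""
    theta, N, L = 100.0, 1000.0, 20.0
    dom = Domain(1, (L,), "periodic")
    xs = np.linspace(0, L, 2001)
    rvals = 1.0 / (1.0 + (xs - 10.0) ** 2)
    dem = Demography(rate_function("constant", 1.0),
                     rate_function("tabulated_x", xs, rvals),
                     rate_function("logistic_F"), theta, N,
                     {k: KernelSpec("gaussian", 1.0, 1)
                      for k in ("gamma", "r", "F")}, validate=False)
    disp = DispersalSpec(theta=theta, dim=1, sigma2=1.0)
    pop = poisson_uniform(N, 1.0, dom, rng)
    x0 = np.array([9.0])
    b_q, c_q = level_coeffs(x0, pop, dem, disp)
    z = rng.standard_normal(10 ** 6) / math.sqrt(theta)
    r_y = np.interp(x0[0] + z, xs, rvals)
    r_x = np.interp(x0[0], xs, rvals)
    from lrpop import local_density
    F = 1.0 - local_density(pop, dem.kernels["F"], x0)
    b_mc = theta * np.mean(r_y - r_x) + F
    se = theta * np.std(r_y - r_x) / math.sqrt(z.size)
    assert b_q == pytest.approx(b_mc, abs=3 * se)
    assert c_q == pytest.approx((theta / N) * np.mean(r_y), rel=1e-3)


# ---------------------------------------------------------------------------
# forward runs


def test_no_births_with_zero_gamma(rng):
    dom = Domain(1, (1.0,), "periodic")
    dem = Demography(rate_function("constant", 0.0),
                     rate_function("constant", 1.0),
                     rate_function("constant", 0.0), 5.0, 50.0,
                     {k: KernelSpec("gaussian", 0.3, 1)
                      for k in ("gamma", "r", "F")})
    disp = DispersalSpec(theta=5.0, dim=1, sigma2=1.0)
    st0 = LookdownState(np.array([[0.5]]), np.array([10.0]), [(1,)], dom,
                        N=50.0)
    st = lookdown_run(st0, dem, disp, 1.0, rng)
    assert not any(ev.kind == "birth" for ev in st.event_log)
    assert st.n == 1
    # with γ = μ_θ = 0 the level ODE is u̇ = 0
    assert st.levels[0] == pytest.approx(10.0)


def test_projection_mass_and_positions(small_logistic, rng):
    dem, disp, dom = small_logistic
    pop = poisson_uniform(dem.N, 1.0, dom, rng)
    st = lookdown_run(LookdownState.from_population(pop, rng), dem, disp,
                      1.0, rng)
    proj = project(st)
    assert proj.total_mass == pytest.approx(st.n / dem.N)
    assert np.array_equal(np.sort(proj.positions[:, 0]),
                          np.sort(st.positions[:, 0]))


def test_projection_distribution_matches_ibm(small_logistic, rng):
    """Total mass at t=1 from lookdown runs is distributed like the direct
    event-driven simulation (projection property)."""
    from lrpop import gillespie_run
    dem, disp, dom = small_logistic
    ibm, ld = [], []
    for _ in range(120):
        pop = poisson_uniform(dem.N, 1.0, dom, rng)
        ibm.append(gillespie_run(pop, dem, disp, 1.0, rng,
                                 record_every=1.0).snapshots[-1].n)
        pop = poisson_uniform(dem.N, 1.0, dom, rng)
        ld.append(lookdown_run(LookdownState.from_population(pop, rng),
                               dem, disp, 1.0, rng).n)
    assert stats.ks_2samp(ibm, ld).pvalue > 0.01


def test_levels_stay_conditionally_uniform(small_logistic, rng):
    """Pooled levels over replicate runs pass a KS test against U[0, N]."""
    dem, disp, dom = small_logistic
    pool = []
    for _ in range(60):
        pop = poisson_uniform(dem.N, 1.0, dom, rng)
        st = lookdown_run(LookdownState.from_population(pop, rng), dem, disp,
                          0.5, rng)
        pool.extend((st.levels / dem.N).tolist())
    assert stats.kstest(pool, "uniform").pvalue > 0.01


def test_higher_death_rate_prunes_more_levels(rng):
    """Raising F pointwise (more net growth → levels pushed down) keeps more
    lines alive on matched seeds; lowering it kills more."""
    dom = Domain(1, (1.0,), "periodic")
    disp = DispersalSpec(theta=5.0, dim=1, sigma2=1.0)
    survivors = {}
    for Fval in (-0.5, 0.5):
        dem = Demography(rate_function("constant", 1.0),
                         rate_function("constant", 1.0),
                         rate_function("constant", Fval), 5.0, 50.0,
                         {k: KernelSpec("gaussian", 0.3, 1)
                          for k in ("gamma", "r", "F")})
        counts = []
        for seed in range(30):
            rr = np.random.default_rng(1000 + seed)
            pop = poisson_uniform(50.0, 1.0, dom, rr)
            st = lookdown_run(LookdownState.from_population(pop, rr), dem,
                              disp, 1.0, rr)
            counts.append(st.n)
        survivors[Fval] = np.mean(counts)
    assert survivors[0.5] > survivors[-0.5]


# ---------------------------------------------------------------------------
# sampling


def test_sample_k_lowest_orders_and_errors(small_logistic, rng):
    dem, disp, dom = small_logistic
    pop = poisson_uniform(dem.N, 1.0, dom, rng)
    st = LookdownState.from_population(pop, rng)
    region = (np.zeros(1), np.ones(1))
    got = sample_k_lowest(st, region, st.n)
    levels = [u for _, _, u in got]
    assert levels == sorted(levels)
    single = sample_k_lowest(st, region, 1)
    assert single[0][2] == min(st.levels)
    with pytest.raises(InsufficientSampleError):
        sample_k_lowest(st, region, st.n + 1)


def test_lowest_level_is_uniform_sample(small_logistic, rng):
    """The spatial law of the lowest-level individual matches a uniformly
    chosen one (exchangeability), by chi-square over spatial bins."""
    dem, disp, dom = small_logistic
    bins = np.linspace(0, 1, 5)
    counts = np.zeros(4)
    n_rep = 400
    for _ in range(n_rep):
        pop = poisson_uniform(dem.N, 1.0, dom, rng)
        st = lookdown_run(LookdownState.from_population(pop, rng), dem, disp,
                          0.3, rng)
        if st.n == 0:
            continue
        x = st.positions[np.argmin(st.levels), 0]
        counts[min(np.searchsorted(bins, x) - 1, 3)] += 1
    # positions are homogeneous, so the lowest level should land uniformly
    assert stats.chisquare(counts).pvalue > 0.01


# ---------------------------------------------------------------------------
# lineages and genealogies


def _run_sampled(rng, T=2.0):
    theta, N = 5.0, 50.0
    dom = Domain(1, (1.0,), "periodic")
    dem = logistic_demography(theta, N, kernel_scale=0.3)
    disp = DispersalSpec(theta=theta, dim=1, sigma2=1.0)
    pop = poisson_uniform(N, 1.0, dom, rng)
    st = lookdown_run(LookdownState.from_population(pop, rng), dem, disp,
                      T, rng)
    return st


def test_trace_lineage_constant_without_births(rng):
    dom = Domain(1, (1.0,), "periodic")
    st = LookdownState(np.array([[0.3]]), np.array([5.0]), [(1,)], dom,
                       N=50.0, time=1.0)
    s, xs = trace_lineage([], st, (1,), 1.0)
    assert np.allclose(xs[:, 0], 0.3)


def test_trace_lineage_jumps_at_kappa0_births(rng):
    st = _run_sampled(rng)
    # find a sampled individual whose label was created with kappa=0
    for ev in reversed(st.event_log):
        if ev.kind == "birth" and ev.kappa == 0 and ev.child_label in st.labels:
            s, xs = trace_lineage(st.event_log, st, ev.child_label,
                                  st.time)
            back = st.time - ev.time
            # the path jumps to the parent's location at that backward time
            k = np.searchsorted(s, back)
            assert any(np.allclose(xs[j, 0], ev.x_parent[0])
                       for j in range(max(k - 1, 0), min(k + 2, len(xs))))
            break
    else:
        pytest.skip("no kappa=0 birth among sampled labels in this run")


def test_genealogy_single_and_cherry(rng):
    dom = Domain(1, (1.0,), "periodic")
    st = LookdownState(np.array([[0.3]]), np.array([5.0]), [(1,)], dom,
                       N=50.0, time=3.0)
    nwk = export_genealogy([], st, [(1,)], T=3.0)
    assert nwk == "(1:3);"


def test_genealogy_parses_and_is_ultrametric(rng):
    import dendropy
    st = _run_sampled(rng, T=2.0)
    sample = sample_k_lowest(st, (np.zeros(1), np.ones(1)), 6)
    labels = [lab for lab, _, _ in sample]
    nwk = export_genealogy(st.event_log, st, labels)
    total_leaves = 0
    for tree_str in nwk.splitlines():
        tree = dendropy.Tree.get(data=tree_str, schema="newick")
        depths = [leaf.distance_from_root()
                  for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, st.time, atol=1e-9)
        total_leaves += len(depths)
    assert total_leaves == 6


def test_genealogy_internal_nodes_at_birth_events(rng):
    """Divergence times in the exported forest coincide with logged birth
    times of the sampled labels' ancestors."""
    st = _run_sampled(rng, T=2.0)
    sample = sample_k_lowest(st, (np.zeros(1), np.ones(1)), 4)
    labels = [lab for lab, _, _ in sample]
    nwk = export_genealogy(st.event_log, st, labels)
    birth_times = {round(ev.time, 6) for ev in st.event_log
                   if ev.kind == "birth"} | {0.0}
    import dendropy
    for tree_str in nwk.splitlines():
        tree = dendropy.Tree.get(data=tree_str, schema="newick")
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            t_node = st.time - max(
                leaf.distance_from_root() for leaf in tree.leaf_node_iter()) \
                + node.distance_from_root()
            assert any(abs(t_node - bt) < 1e-6 for bt in birth_times)


# ---------------------------------------------------------------------------
# limit mode


def test_limit_mode_alpha_zero_no_new_lines(rng):
    dom = Domain(1, (1.0,), "periodic")
    dem = logistic_demography(5.0, 50.0, kernel_scale=0.3)
    disp = DispersalSpec(theta=5.0, dim=1, sigma2=1.0)
    pop = poisson_uniform(50.0, 1.0, dom, rng)
    st0 = LookdownState.from_population(pop, rng, mode="limit", alpha=0.0,
                                        u_max=50.0)
    st = lookdown_run(st0, dem, disp, 1.0, rng)
    assert not any(ev.kind == "birth" for ev in st.event_log)


def test_limit_mode_first_gap_is_exponential(rng):
    """Creations form a Poisson process with intensity 2αγr per unit level
    and time, so the lowest gap created in a window of length W is
    Exp(2αγr·W).  Choosing F = αγr·u0 pins the parent's level at the fixed
    point of u̇ = αγr u² − F u, so gaps are measured from a constant level."""
    alpha, W, u_max, u0 = 0.8, 0.3, 12.0, 1.0
    dom = Domain(1, (1.0,), "periodic")
    dem = Demography(rate_function("constant", 1.0),
                     rate_function("constant", 1.0),
                     rate_function("constant", alpha * u0), 5.0, 50.0,
                     {k: KernelSpec("gaussian", 0.3, 1)
                      for k in ("gamma", "r", "F")})
    disp = DispersalSpec(theta=5.0, dim=1, sigma2=1.0)
    gaps = []
    for seed in range(250):
        rr = np.random.default_rng(seed)
        st0 = LookdownState(np.array([[0.5]]), np.array([u0]), [(1,)], dom,
                            mode="limit", alpha=alpha, u_max=u_max)
        st = lookdown_run(st0, dem, disp, W, rr, dt_max=0.01)
        births = [ev for ev in st.event_log if ev.kind == "birth"
                  and ev.parent_label == (1,)]
        if births:
            gaps.append(min(ev.u_new for ev in births) - u0)
    rate = 2 * alpha * W
    assert len(gaps) > 50
    assert stats.kstest(gaps, "expon", args=(0, 1.0 / rate)).pvalue > 0.005


def test_limit_mode_projection_recovers_intensity(rng):
    """Poisson(λ·u_max) lines below the ceiling project to mass ≈ λ."""
    dom = Domain(1, (1.0,), "periodic")
    lam = 2.0
    for u_max in (50.0, 400.0):
        n = rng.poisson(lam * u_max)
        st = LookdownState(rng.uniform(0, 1, size=(n, 1)),
                           rng.uniform(0, u_max, size=n),
                           [(i,) for i in range(n)], dom, mode="limit",
                           alpha=0.0, u_max=u_max)
        mass = project(st).total_mass
        assert mass == pytest.approx(lam, abs=4 * math.sqrt(lam / u_max))
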
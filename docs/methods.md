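# Methods

## The model

The population is a cloud of point individuals in a 1D or 2D habitat,
encoded as the atomic measure η = X/N (mass 1/N per individual, so that a
nominal occupancy of N individuals per unit volume corresponds to density
one).  Three density-dependent quantities drive the dynamics, each reading
the local density through its own smoothing kernel:

* **birth**: an individual at x produces one juvenile at rate
  γ(x, ρ_γ\*η(x)) per unit unscaled time;
* **establishment**: the juvenile lands at y = x + b(x)/θ + K(x)z/√θ
  (z standard normal, KKᵀ = C) and survives with probability
  r(y, ρ_r\*η(y)), evaluated on the pre-birth population — maturity is
  instantaneous and failed juveniles never enter the state;
* **death**: the per-capita death rate is defined through its deviation
  from rγ as μ_θ = rγ − F(x, ρ_F\*η(x))/θ, so that the net per-capita
  reproductive rate, times θ, is exactly F.

Time is scaled by θ: all package APIs quote rates and horizons in scaled
time, where per-capita birth and death rates are θγ and θμ_θ.  The ratio
α = θ/N controls how demographic noise survives the large-N limit: the
package simulates finite (θ, N) directly and represents the deterministic
limit through the PDE solvers; the measure-valued stochastic limit itself
(α > 0 as N → ∞) is exercised only through the finite-N particle system
and the limit-mode lookdown.

Individuals do not move during their lifetime, have no age structure, and
reproduce uniparentally — the natural targets are microbial colonies or
selfing plants.

Rate functions live in a closed registry (`constant`, `logistic_F` =
1 − m, `bistable_F(s)` = (1 − m)(2m − 1 + s), `linear_gamma` (γ = m with a
configurable cap, default 20, respecting the boundedness the theory
needs), `saturating_gamma(a, b)` = a/(b + m), and tables in m or in x), so
configurations serialize to plain text and μ_θ ≥ 0 can be validated on a
declared admissible density range before a run starts.  For the
density-dependent-motility preset (r = 1, γ = m, F = 1 − m) one has
μ_θ = m(1 + 1/θ) − 1/θ, which is negative below m = 1/(θ + 1); that preset
therefore declares the admissible range [1/(θ+1), m_max].  A negative death
rate encountered at run time raises — it is never clipped — because it
signals parameters outside the model's assumptions.

## Forward simulation

`gillespie_run` is exact: every individual's birth and death rate is
recomputed from the current configuration at every event (O(n) kernel sums
per event — correctness over speed), the next event is exponential with
the total rate, and establishment is decided at the landing point.
`discrete_step` is the synchronous variant: p_birth = 1 − e^{−θγ dt},
p_death = 1 − e^{−θμ_θ dt} with all densities frozen at the start of the
step and offspring appended after all decisions, making the update
order-independent; a warning fires when θ·dt·max(rates) is not small.

Local densities can be evaluated by the exact pairwise minimal-image sum
or, on periodic 1D domains, by depositing atoms on a grid (cloud-in-cell)
and convolving with the kernel by FFT.  Grid kernels are *cell-averaged*
through the kernel CDF rather than point-sampled: point-sampling a
discontinuous kernel (the top-hat) effectively widens its support by
O(dx), which measurably distorts the dispersion relation near the sinc
zeros.  An individual's own atom contributes ρ(0)/N to its local density
(the convolution has no self-exclusion).  Periodic boundaries are the
default — they match the homogeneous-equilibrium analyses and avoid edge
effects; the hard population cap defaults to 100·N·volume and violating it
raises an explosion error with diagnostics.

## Lookdown construction

Each individual carries a level u.  In the finite-N representation levels
are conditionally i.i.d. Uniform[0, N] given positions; births are
proposed at rate 2θ(1 − u/N)γ (thinned against the bound 2θγ_max), the new
level is Uniform[u, N], and a fair coin κ decides whether parent or
offspring takes it; the line of descent follows the *old* level, and a
fresh Ulam–Harris label goes to whoever received the new one.  Between
events the level solves u̇ = c u² − b u with

    c = (θ/N) γ ∫ r(y,η) q_θ(x,dy),
    b = θγ ∫ (r(y,η) − r(x,η)) q_θ(x,dy) + F(x,η),

integrals by Gauss–Hermite quadrature (20 nodes per axis; the integral
term vanishes identically for spatially constant r).  The ODE linearizes
in v = 1/u, so each piece has an exact closed form, including the time at
which a level crosses the killing cap N.  Coefficients are frozen between
events (they can only change at events, where positions change); a
maximum step of 0.01/θ scaled time forces refreshes in event-sparse
phases, and the thinning acceptance carries a factor n/n_pre correcting
the proposal bound for deaths that occurred while levels advanced across
the interval.  Projecting (forgetting levels, mass 1/N per atom)
reproduces the plain birth–death process in distribution — checked
against `gillespie_run` by two-sample KS on 500-replicate totals — and
levels remain uniform, which is what makes "the k lowest levels in a
region" a uniform k-sample.

In limit mode (parameter α = lim θ/N) lines of descent move as diffusions
dX = β dt + J dW with β = rγ(b + C∇log r), JJᵀ = rγC; levels follow
u̇ = αγr u² − (γ𝓑r + F)u; and new lines appear as a Poisson process with
intensity 2αγr per unit level above the parent, truncated at a tracking
ceiling u_max (an Euler scheme with step 0.01).  With α = 0 no new lines
are ever created.  The truncation means lines near u_max may matter if
they later descend; the package reports no theoretical bound — doubling
u_max and comparing sampled-lineage statistics is the recommended
diagnostic.

Genealogies: the event log records every birth (parent/child labels,
locations, new level, κ).  Tracing a sampled individual backwards, the
lineage jumps to the parent's location exactly when the sampled line held
the offspring role at that event (κ = 0 if it is the new label, κ = 1 if
the old label followed the offspring).  `export_genealogy` computes
pairwise divergence times as the latest event time below which two
ancestor-label paths coincide (labels are evaluated just below segment
boundaries to avoid ambiguity at event times), single-links them into a
forest, and emits Newick with branch lengths in scaled time; trees are
ultrametric at the sampling time by construction.

## PDE solvers

All solvers are explicit — transparency and testability over speed — with
CFL guards that raise with a suggested step:

* classical reaction–diffusion ∂ₜφ = (σ²/2)∂ₓₓφ − b∂ₓφ + φF(φ):
  second-order central Laplacian, first-order upwind drift, Heun time
  stepping, guard σ²dt/dx² ≤ 0.4;
* porous-medium + logistic ∂ₜφ = ∂ₓₓ(φ²) + φ(1 − φ): central Laplacian of
  φ², forward Euler with the adaptive bound dt ≤ 0.2·dx²/(2·max 2φ);
  negative undershoots are clipped at zero and the clipped mass is
  accounted (it must stay below 10⁻⁸ of the total).  No preferred scheme
  exists for this degenerate diffusion; the front-location bias of this
  one is measured empirically (speed within 0.03% of the analytic wave on
  the default grids), not bounded;
* nonlocal equation ∂ₜφ = r(ρ_r\*φ)𝓑\*(γ(ρ_γ\*φ)φ) + φF(ρ_F\*φ):
  convolutions by FFT (periodic only), the CFL guard using the
  instantaneous max of r·γ as effective diffusivity.  𝓑\* is implemented
  with spatially constant b and C, which covers every wave and clumping
  analysis here.

Travelling waves: the Allen–Cahn profile w = (1 + eˣ)⁻¹ (speed s) and the
sharp porous-medium profile w = (1 − e^{x/2})₊ (speed 1) are closed forms
whose co-moving residuals vanish identically (verified analytically); the
Fisher-KPP minimal-speed profile is realized dynamically by relaxing a
Heaviside front in the c = 2 co-moving frame (default domain [−40, 40],
dx = 0.02; dynamic selection rather than shooting, mirroring how the
minimal speed is selected in the time-dependent problem).  Fronts are
tracked at level 0.5 — well-defined for sharp and smooth fronts alike —
and speeds are ordinary least-squares slopes of front position against
time.  A deliberate caveat for interpreting speed tests: from a Heaviside
start the front speed approaches 2 like 2 − O(1/t), so a finite window
reads slightly below 2 (about 1.5% over t ∈ [50, 150]); the acceptance
tolerance absorbs this.

## Ancestral lineages

With isotropic dispersal the backward-time lineage generator is
(σ²/2)rγ[Δ + (2∇log(γφ) − 2b/σ²)·∇] in the lab frame, plus (c − rγb)·∇ in
a frame co-moving at speed c.  Wave-frame coefficients for the three
reference waves are closed-form; lab-frame coefficients come from a
gridded φ with ∇log(γφ) by central differences on log-transformed values
(floor 1e−300; coefficients requested where γφ is nonpositive raise
rather than clip).  Simulation is Euler–Maruyama on dX = drift dt +
√(2a) dW.  At the degenerate porous-medium front (a(0) = 0) paths are
reflected at −10⁻⁶; the speed measure vanishes there, so the boundary
treatment has vanishing stationary impact (halving the offset does not
move the occupation KS statistic at the resolution tested).

Speed measures m ∝ a⁻¹exp(∫ drift/a) are used in closed form where
available — m_A ∝ e^{sx}(1 + eˣ)⁻², m_P = 3e^ξ(1 − e^{ξ/2}) on ξ < 0 (the
constant 3 is 1/∫e^ξ(1 − e^{ξ/2})dξ) — and by quadrature on a grid
otherwise, with non-integrability (the pulled Fisher-KPP wave) reported
as an outcome, not an error.  Only normalized densities are exposed; the
overall constant of the reversible lab-frame measure (γ/r)φ²e^{−2h/σ²} is
not.  Long-term reproductive value is returned as the normalized ratio
π/φ.  Multiplying r and F by a spatial factor λ(x) leaves stationary
profiles untouched but multiplies the lineage generator by λ — the
package's identifiability demonstration shows the occupation law shifting
into λ < 1 regions while the density profile stays flat.

## Clumping analysis

Around a constant equilibrium φ₀ (F(φ₀) = 0, F′(φ₀) < 0, found by
bisection) the linearized nonlocal equation gives a per-mode growth rate

    λ(u) = −u²σ²φ₀r₀γ₀′ ρ̃_γ(u) − u²σ²r₀γ₀ + φ₀F₀′ ρ̃_F(u),

with σ² the diffusivity (𝓑 = σ²Δ, dispersal variance 2σ²).  Two kernel
transform conventions coexist in the literature; the package's default
("dynamical") uses ρ̃ normalized to ρ̃(0) = 1, which is the factor the
convolution theorem inserts and therefore the one that matches measured
mode growth in `solve_nonlocal` (verified to 10%); the alternative
(`convention="paper"`) keeps a 1/(2π) on the kernel factors only, as the
relation is sometimes displayed.  Because the conventions differ by
positive constants on individual terms, which σ²/ε² values destabilize a
given demography differs between them; every package analysis and default
uses the dynamical one.  A top-hat competition kernel of half-width ε has
ρ̃_F(u) = sin(εu)/(εu) < 0 on (π/ε, 2π/ε), so short-range dispersal
(σ²/ε² small) opens an unstable band there: discrete patches spaced by
roughly the interaction distance.  Unstable intervals are bracketed by
bisection on a wavenumber grid, and `predicted_vs_observed_wavelength`
closes the loop by growing a 10⁻³ white-noise perturbation to saturation
and reading the dominant wavelength off the power spectrum (within 20% of
2π/u*, the residual being nonlinear wavelength selection).  Whether a
given saturating-birth demography is linearly unstable is always decided
numerically from λ(u), never from a closed-form inequality.  2D dispersion
(Bessel transforms of disks) is a documented extension, not implemented.

## Synthetic initial conditions and what the tests show

Initial populations are homogeneous Poisson clouds at a declared scaled
density (so tests start in the exchangeable, spatially homogeneous regime
the equilibrium analyses assume), block/Heaviside profiles for invasion
fronts, and sampled closed-form wave profiles.  These fixtures emulate
demographic equilibrium and clean invasions; they do not emulate
environmental heterogeneity, clustering in the initial state, or
observation noise, so the passing tests certify the internal consistency
of the model chain (particles → nonlocal PDE → local PDE → lineages), not
agreement with any field data.

Default study conditions used by the distributional checks were chosen
once for statistical resolution at tractable cost: the lookdown/IBM
comparison runs the logistic preset at θ = 5, N = 50 on a unit periodic
habitat (≈50 individuals, 500 replicates per arm); the discrete-time
equilibrium run uses θ = 10, N = 100, length 50, kernel scale 1,
dispersal sd 1/√θ, step 0.05 per-θ time units to horizon 50, averaging
the smoothed density at individuals over the second half; lineage
ensembles use 200 paths to backward horizon 200 with burn-in 50 (Allen–
Cahn step 0.01; porous-medium 0.005 for the degenerate boundary).

## Numerical conventions, ties, degenerate inputs

* `kernel_fourier` keeps the 1/(2π)-prefactor convention (ρ̂(0) = 1/(2π));
  all sign and band-boundary conclusions are invariant to this constant.
* Empty populations are absorbing everywhere; empty regions raise on
  sampling; a field that never crosses the tracking level raises
  front-not-found; a non-integrable speed measure is a reported outcome.
* `front_position` takes the *rightmost* interpolated crossing (rightward-
  moving fronts), breaking ties toward the tip.
* Stochastic runs are pure functions of (configuration, seed): one
  `numpy` Generator drives each run.
* Levels at exactly the cap are treated as dead; the closed-form crossing
  time is used, not a discretized check.

## Known limitations

* Event-driven simulation recomputes all rates exactly at every event;
  cost grows as O(n²) per unit time, so it is a reference implementation
  for hundreds, not millions, of individuals; the discrete-time driver
  with FFT densities is the large-population workhorse.
* Lookdown limit mode assumes isotropic dispersal and reports truncation
  diagnostics only through the u_max-doubling heuristic.
* The nonlocal solver requires periodic boundaries; spatially varying
  dispersal coefficients are accepted by the local solver only through
  conservative-form differencing and are untested beyond smoke level.
* The measure-valued superprocess regime (α > 0, N → ∞) is represented
  only by finite-N simulation; no numerical scheme for the limit object
  itself is provided.
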
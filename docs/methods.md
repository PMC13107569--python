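# Methods

## Model and assumptions

The package models one non-centrosomal microtubule as the interval
[L₋(t), L₊(t)] on a one-dimensional axis (appropriate for neurites, where
the dynamics of interest are longitudinal).  Two depolymerase species are
tracked as continuum densities, each split into a lattice-bound, moving
state and an unbound, cytoplasmically diffusing state exchanging at first-order
rates.  The mean-field advection–diffusion form is the standard
quasi-steady-state reduction of a stochastic switching-particle description;
motor–motor exclusion, discrete lattice effects, and explicit
catastrophe/rescue state switching are outside scope — the tip laws describe
*net* end dynamics, with length-dependent catastrophe absorbed into the β±
terms.

Densities are nondimensional, normalized so the boundary reservoir value
is 1.  Consequently γ± (tip depolymerization speed per unit density) carries
µm/s per unit normalized density.  At the minus end the bound plus-motor and
both free densities are reservoir-pinned (Dirichlet, value 1) and the bound
minus-motor has zero Fickian flux (it exits ballistically); the plus end is
the mirror arrangement.

## Parameters (µm, s)

| parameter | plus motor | minus motor | meaning |
|---|---|---|---|
| v | 0.05 | 0 | walking speed on the lattice |
| D_on | 0.01 | 0.38 | diffusivity while bound |
| D_off | 4 | 4 | cytoplasmic diffusivity |
| k_on | 1 | 1 | binding rate (baseline; measured values are per motor concentration, which the model does not track) |
| k_off | 0.25 | 1.2 | unbinding rate; the minus motor's published range is 1.2–3 s⁻¹ and the default is the lower bound, which keeps it longest-lived on the lattice |

Tip kinetics: α₊ = 0.15, α₋ = 0.02 µm/s (maximal growth speeds of 9 and
1.125 µm/min converted to seconds; the minus-end value is rounded from
0.01875), β₊ = 0.05, β₋ = 0.0006 s⁻¹, γ₊ = γ₋ = 0.01.  The characteristic
length is L̄ = 10 µm.  `beta_from_avg_growth` exposes the exact derivation
arithmetic β = (α − v_avg/60)/L̄; note the exact quotients are 0.005 and
0.000625 s⁻¹, while the tabulated scenario values above are the published
rounded/tabulated ones (0.05 and 0.0006) — the scenarios deliberately use
the tabulated values so the shipped regimes are reproduced as published.
`validate_params` warns when k_on, k_off are not large against v/L̄ and
D/L̄², the regime the reductions assume.

## Numerical scheme

**Moving domain.** The ALE map x = L₋ + ξL, ξ ∈ [0,1], converts the
problem to a fixed reference grid; each field gains a mesh-motion advection
term with node velocity ẋ(ξ) = dL₋/dt + ξ(dL₊/dt − dL₋/dt).

**Space.** n_cells + 1 nodes (default 100 cells).  Diffusion:
second-order central.  Advection: first-order upwind on the *total* velocity
(physical − mesh) by default, chosen for positivity of the full-model
densities; a `central` option exists and is appropriate when the cell Péclet
number is small (it is used in tests that compare the reduced PDE against
closed-form profiles to second-order accuracy).

**Boundary rows.** Dirichlet nodes carry zero time derivative, so they hold
their value to machine precision at every accepted step.  Zero-gradient
nodes copy the neighbouring node's derivative (the first-order one-sided
gradient is then exactly conserved).  The reduced model's Robin nodes use
second-order one-sided stencils and evolve by the exact time derivative of
the discrete constraint plus a stiff relaxation toward the constraint
manifold (rate D/Δx²), so integration error cannot accumulate off it.

**Robin orientation.** The minus-end condition on the total minus-motor
density, h + ∂h/∂n = 1 with a 1 µm gradient coefficient, is implemented
with the gradient along the outward normal (h − ∂h/∂x = 1 in coordinates).
The uniform steady state h ≡ 1 satisfies the condition under either sign,
but only the outward-normal reading is dissipative: with the inward sign
the linearized problem u_t = D u_xx, u_x(0) = −u(0), u(L) = 0 has a
positive eigenvalue whenever L > 1 µm (tanh(µL) = µ·1 µm has a positive
root), so no relaxation to the uniform state would exist.

**Plus-end flux datum.** The reduced q-equation's condition
𝒱₊q − 𝒟₊∂q/∂x = rhs at L₊ is exposed as `q_robin_rhs` (default +1, the
reservoir value).  The closed-form profile used throughout the adiabatic
analysis, q(x) = (1 + 1/𝒱₊)e^{𝒱₊x/𝒟₊} − 1/𝒱₊, satisfies the condition with
rhs = −1; `robin_steady_profile` gives the general solution for any rhs
(linear in x when 𝒱₊ = 0, where the exponential form is undefined).  Both
conventions are kept because the analysis layer and the printed boundary
data are mutually inconsistent by this sign; the package does not silently
reconcile them.

**Time.** The concatenated state (all field nodes + L₋ + L₊) is integrated
with BDF (scipy `solve_ivp`), rel_tol 10⁻⁶ / abs_tol 10⁻⁹, with an explicit
Jacobian sparsity pattern (per-field bands, the partner-field diagonal, and
dense coupling columns for the tip positions and the two tip-adjacent
density nodes).  One automatic retry tightens tolerances 100× before a
failure is raised.

**Termination.** Runs stop at L ≤ L_min = 0.1 µm ("disassembled"; the
transformed equations are singular as L → 0) or L ≥ L_max = 100 µm
("runaway").

**Initial conditions.** Uniform density 1 by default (matching the
reservoirs minimizes start-up boundary layers); `zero-interior` and custom
profiles are available for relaxation studies.

**Root finding.** The adiabatic equilibrium is located by bracketed Brent
iteration on the scalar length flow (f strictly decreasing, g strictly
increasing make the bracket robust; the upper end expands geometrically).
The fixed-end coincidence condition uses the principal Lambert-W branch,
whose argument is positive for positive parameters.

## Verification strategy

- closed-form oracles: motor-decoupled runs (γ = 0) against the exact
  exponential length relaxation; uniform-field reaction arithmetic; the
  steady q and h profiles.
- an independent continuum oracle (steady boundary-value solves of the
  coupled species pairs via collocation) reproduces the solver's steady tip
  densities p(L₊) ≈ 3.997 and m(L₋) ≈ 0.834 at L = 10 µm — these two
  numbers are exactly what make the tuned treadmilling (β₊ = 0.0116 s⁻¹)
  and fixed-ends (β₊ = 0.011, β₋ = 0.00117 s⁻¹) scenarios balance at 10 µm.
- brute-force sign scans for equilibrium uniqueness; finite-perturbation
  comparative statics; grid-refinement checks on every shipped scenario.

Problem sizes: shipped scenarios run at 100 cells for 300–600 s horizons;
convergence checks double to 200 cells; quick oracle tests use 24–64 cells.

## Known limitations and honest discrepancies

- **Complete disassembly is unreachable at the shipped parameters.**  The
  steady tip densities saturate (p(L₊) ≲ 4, m(L₋) ≲ 0.9 at the baseline
  kinetics), so motor-driven tip loss is bounded by
  γ₊p + γ₋m ≈ 0.08 µm/s < α₊ + α₋ = 0.17 µm/s.  The baseline
  "disassembly" run therefore shrinks fast and near-linearly from 10 µm but
  relaxes to a stable ≈ 2.4 µm treadmilling state rather than vanishing,
  and the Patronin-knockdown run (γ₋ = 0.05) relaxes to ≈ 7.2 µm — both
  ends then translate together at +0.026 µm/s, a poleward-flux-like
  treadmill.  Driving the length to zero requires γ-weighted tip densities
  exceeding the total intrinsic growth, e.g. γ₋ ≳ 0.17 at these kinetics.
- **Full vs reduced normalization.**  The full model pins each species at 1
  at its reservoir (totals 2), the reduced model pins the totals at 1, and
  the plus-end outflow data differ structurally; the sup-norm distance
  between full totals and reduced fields therefore does not vanish — or even
  decrease — as switching is made faster at fixed ratio.  The reduced model
  is a tool for qualitative phase structure (existence dichotomy, monotone
  comparative statics, treadmilling genericity), all of which the full model
  reproduces; it is not a quantitative surrogate at tip resolution.
- The adiabatic length ODE tracks the full model with 100× accelerated
  kinetics to within ≈ 0.8 µm along the transient and ≈ 3% in asymptotic
  length at the baseline; the residual gap is the boundary-normalization
  effect above acting on the tip density.
- First-order upwind advection limits interior spatial accuracy to O(Δx) in
  the default configuration; all shipped-scenario length observables change
  by < 0.004 µm between 100 and 200 cells.
- The classification rule has no "shrinking" label by design: a run still
  relaxing toward its equilibrium when the horizon ends is reported
  `indeterminate` rather than guessed.
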
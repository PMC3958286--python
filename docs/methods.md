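# Methods

## Model

Six fields on 0 ≤ x ≤ a₄ (electrode at x = 0): substrate s, oxidized
and reduced mediator m_ox / m_red, oxygen o (mobile, all four layers),
and the immobile enzyme forms e_ox / e_red (enzyme layer only,
0 ≤ x ≤ a₁). Governing equations are mass-action reaction terms plus
Fick diffusion with per-layer diffusivities:

* enzyme layer: ∂e_ox/∂t = −k₁e_ox s + k₂e_red m_ox (e_red the
  negative), ∂s/∂t = D∂²s − k₁e_ox s, mediator and oxygen carry the
  k₂ and k₃ terms;
* PVA, terylene and diffusion layers: diffusion only, except the
  mediator–oxygen reaction k₃ m_red o, which runs everywhere.

Boundary conditions: bulk Dirichlet values at x = a₄ (s₀, m₀, 0, o₀);
at the electrode m_red = 0 (the electrode reaction is taken as
infinitely fast), zero flux for s and o, and a flux mirror for m_ox
(the electrode produces one M_ox per M_red consumed). At internal
interfaces both concentration and diffusive flux are continuous.
At t = 0 the bulk species exist only at the outer boundary node, o is
uniform at o₀, and the enzyme is fully oxidized — the moment the
sample is added.

Products (gluconolactone, HO₂⁻) feed back into nothing and are not
tracked. No reverse reactions, no enzyme inactivation, no temperature,
pH or potential dependence: rate constants are those of the fixed
operating point (20 °C, 0.4 V).

## Parameters

`default_parameters()` is the reference sensor. Strict SI throughout.
Highlights, with why they matter:

| symbol | default | role |
|---|---|---|
| d₁..d₄ | 5, 1, 12, 150 µm | layer thicknesses; d₄ sets the dominant diffusion time d₄²/D ≈ 50 s |
| k₁ | 8.1×10² m³ mol⁻¹ s⁻¹ | enzyme reduction by glucose |
| k₂ | 6.7×10⁴ m³ mol⁻¹ s⁻¹ | enzyme reoxidation by M_ox; k₂e₀ ≈ 67 s⁻¹ is the stiffest kinetic scale |
| k₃ | 1.8×10⁻¹ m³ mol⁻¹ s⁻¹ | mediator + O₂; the quantity under study |
| e₀ | 10⁻³ mol/m³ | total enzyme |
| s₀, m₀ | 4.98, 0.05 mol/m³ | bulk glucose and mediator |
| o₀ | 2.53×10⁻⁷ mol/m³ | dissolved-O₂ reference for aerobic runs |
| A, n_e, F | 4.5×10⁻⁶ m², 2, 96486 C/mol | current scale |

Two oddities of the reference set are kept deliberately rather than
"corrected": o₀ is far below typical air-saturation values, and O₂
diffuses equally fast in all four layers. Both are exposed as
ordinary parameters; B_O2 scales essentially linearly in o₀, so users
who prefer another oxygen reference can rescale.

## Discretization

Each layer carries `points_per_layer` uniform intervals; interface
nodes are shared (4·n+1 nodes). Time stepping is backward Euler. The
bilinear reaction terms are linearized by lagging the partner species
(k·u·v → k·u_new·v_lag) and re-sweeping (Picard) until the relative
change is below `picard_tol` (10⁻⁸); each sweep is four banded solves
(s, m_ox, m_red, o, in the causal order of the reactions) plus a
pointwise 2×2 enzyme update whose algebra conserves e_ox + e_red
*exactly*, step by step.

Row construction:

* interior rows: standard second difference;
* interface rows: finite-volume balance over the two half-cells —
  D_i(u_j−u_{j−1})/h_i vs D_{i+1}(u_{j+1}−u_j)/h_{i+1} — with the
  node's reaction term weighted by the half-cell widths; this enforces
  flux continuity conservatively across the diffusivity jump;
* electrode: mirror-ghost (second-order) zero-flux rows for s and o;
  m_red pinned to 0; for m_ox an algebraic row equating its inbound
  flux to the outbound m_red flux, written with the same one-sided
  second-order stencil (−3u₀+4u₁−u₂)/(2h) that the current
  computation uses, so the discrete current and the discrete boundary
  condition agree by construction (the row makes the m_ox system
  bandwidth (1,2); it is solved directly by LAPACK gbsv);
* bulk edge: Dirichlet rows, re-pinned exactly after each solve
  (partial pivoting otherwise leaves ~10⁻¹⁶ residue).

Halting: at each step the dimensionless decay rate (t/i)|Δi/Δt| is
tested against ε (default 10⁻²); the test is suppressed while the
current is below `current_floor_fraction` (10⁻³) of its running
maximum, because the criterion is meaningless while i ≈ 0 during the
transport lag. If the test never fires, the run stops at `t_max` with
a logged warning and `t_r = NaN`.

Defaults and the sizes used: `SolverOptions` defaults to the reference
50 points/layer and dt = 10⁻³ s. Production runs in the tests,
examples and acceptance script use dt = 0.01 s: steady-state readouts
are fixed points of the scheme and therefore dt-independent (measured
i_st and profile changes between dt = 0.02/0.01/0.005 are < 0.02%),
and dt only shifts where along the plateau the halting rule fires.
Sweep-style studies run at 10 points/layer, dt = 0.05 s (see below for
why that is safe). `picard_max_iter` defaults to 60: the lagged
enzyme–mediator coupling contracts at roughly (k₂e₀dt)/(1+k₂e₀dt) per
sweep, ≈ 0.77 at dt = 0.05, so reaching 10⁻⁸ needs more than the
~20 sweeps that suffice at small dt.

Degenerate inputs: all-zero bulk concentrations are a fixed point;
s₀ = 0 yields an identically zero current and a t_max halt; negative
concentrations beyond −10⁻¹² abort the step (backward Euler with
implicit loss terms keeps fields nonnegative in practice; tiny
round-off undershoots are clamped to zero).

## The oxygen-sensitivity protocol

B_O2 differences two currents that agree to ~10⁻⁸ relative, far below
the discretization error of either run alone. Both runs therefore use
the identical grid and time step, are stepped in lockstep, and are
read at the same final time — the first step at which *both* satisfy
the decay-rate test with ε tightened to 10⁻⁴. Discretization error
then cancels between the branches: B_O2 at the reference parameters
moves by < 1% between 10 and 50 points/layer, which is what licenses
the coarse sweep configuration. Reading both runs at per-run response
times instead would inject halting-time quantization of order
ε·dt/t_r ≈ 10⁻⁶ relative — larger than the signal itself, and a
plausible explanation for why order-of-magnitude statements about
B_O2 are best treated as bounds.

Exact identities the implementation preserves: k₃ = 0 (or equal o₀ in
both branches) gives B_O2 = 0 *exactly*, because both branches then
execute bitwise-identical arithmetic; an anaerobic run is bitwise
identical to a k₃ = 0 run, since a zero oxygen field annihilates
every k₃ term.

## Verification

A method-of-lines reference integrates the *same* spatial operator
(shared `Discretization` object: identical interior, interface,
boundary rows and current stencil) with SciPy's adaptive BDF at
rtol = 10⁻⁸ and per-species absolute tolerances. Agreement with the
implicit solver on coarse configurations is ~10⁻⁴ relative in the
current (tested against a 1% band), and improves as dt is refined —
this isolates the time-integration error. Spatial correctness is
checked separately: the discrete operator annihilates the
constant-flux piecewise-linear multilayer profile to machine
precision, and with all reactions off the solver relaxes to the exact
(constant) steady diffusion solution to better than 10⁻¹⁰.

## What the simulations do and do not show

Everything here is simulation of the stated model; the package ships
no experimental data. Passing tests demonstrate that the scheme
solves *this* model accurately and that the model reproduces the
reported steady-state depletions and sensitivity tendencies — not
that the model captures every real electrode: at high and low
mediator concentrations real sensors deviate from it, plausibly
through reverse reactions, compound instability or
concentration-dependent rate "constants", none of which are
modelled. Calibration-curve machinery is provided, but fitting rate
constants to experimental transients is out of scope.

Known limitations: 1-D planar geometry only; convection enters only
as the Nernst cutoff at a₄; the electrode reaction is infinitely fast
(m_red = 0 there); no product fields; first-order accuracy in time
(by design, for unconditional stability and the paired-run
cancellation), second-order in space.
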
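# Methods

## Model and discretization

The simulator advances the membrane potential V(x, t) on a branched
neurite discretized into cylindrical elements.  Both membrane models are
written as A ∂²V/∂x² = B ∂V/∂t + C·V + D and then lumped per element of
length Δx, diameter d and membrane thickness h:

* axial: r̂_a = 4ρ_a/(πd²) (Ω/m); the link resistance between neighbours of
  unequal size uses half-lengths in series,
  r_link(i, pa) = (r̂_a,i Δx_i + r̂_a,pa Δx_pa)/2, the standard second-order
  treatment of a nonuniform grid that reduces to r̂_a Δx on uniform chains;
* capacitance: ĉ_m = [h/(C_m πd) + Σ_k h_my/(C_my π d_my^k)]⁻¹ with
  d_my^k = d + 2h + 2(k−1)h_my — the membrane shell and each myelin layer
  are capacitors in series (the sum is empty for bare membrane);
* passive resistance: r̂_m = ρ_m h/(πd) + Σ_k ρ_my h_my/(π d_my^k);
* HH conductances are lumped as g = πdGΔx/h with G_Na = Ḡ_Na m³h,
  G_K = Ḡ_K n⁴.

C_m, C_my are permittivity-style electric constants (F/m): capacitance per
area = C/thickness.  Likewise conductivities (S/m) divide by h to give
per-area conductances.  This keeps every geometric dependence explicit, so
mechanical rescaling of (Δx, d) propagates into the circuit without
re-deriving per-area constants.

The element tree is enumerated soma-to-tips in a depth-first preorder that
always descends the first ("right") child before the second ("left") one,
so a branching element b has rc = b+1 and parents always precede children.
A terminal's rc points to itself; branching at element 0 is disallowed
(the root row carries the sealed-end constraint).  SWC reconstructions are
adapted to this scheme on load: each parent→child sample segment becomes
⌈len/Δx_target⌉ elements of diameter 2·r_child, n-furcations are expanded
into cascades of binary branchings joined by ≤ 0.1 µm connector elements,
and a connector lead-in is inserted if the first element would otherwise
branch.  3D coordinates survive only as arc length and topology.

### Gating kinetics

Rates are evaluated in the classic mV/ms convention with v = V − V_rest:
α_m = 0.1(25−v)/(e^{(25−v)/10}−1), β_m = 4e^{−v/18},
α_h = a_h e^{−v/20}, β_h = 1/(e^{(30−v)/10}+1),
α_n = 0.01(10−v)/(e^{(10−v)/10}−1), β_n = 0.125 e^{−v/80};
removable singularities are evaluated by their limits via x/expm1(x).
The gating ODE is integrated as dx/dt = α(1−x) − βx (the only sign
convention with a stable fixed point in (0,1) and consistent with the
E_L rest condition), forward Euler, clamped to [0,1] — the clamp guards the
invariant at aggressive but stable time steps.  The inactivation prefactor
a_h is configurable (`alpha_h_scale`); the default is the classic 0.07
ms⁻¹ (0.007, which appears in some transcriptions, makes inactivation 10×
too slow and breaks spike repolarization timing).

E_L is computed once from the rest-state conductances and then frozen for
the whole run, including under mechanical loading (ion homeostasis is
assumed to track slow concentration changes).

## Time integration

**Explicit** — forward Euler on the compartmental ODEs; boundary
conditions applied by overwrite after each step (V_0 ← V_1,
V_tip ← V_parent), then the gates advance at Vⁿ⁺¹.

**Implicit** — backward Euler with (W, K) frozen at Vⁿ (semi-implicit
linearization keeps one linear solve per step).  The matrix is
quasi-tridiagonal: per element α = −g_pa, δ = −g_rc, γ = −g_lc (branchings
only) and diagonal β = ĉ_mΔx/Δt − WΔx + Σg; a branching between k, k+1 and
l shows up as γ at (k, l) and α at (l, k).  Boundary rows are equality
constraints (1, −1 | 0) with the neighbouring coupling folded onto the
diagonal, which keeps the matrix nonsingular and makes sealed ends exact in
the solution; on a 2-element chain only the root constraint is applied.
Systems are solved by sparse LU (SuperLU); the factorization is cached
across steps for purely passive trees.  The residual is checked against
`linear_tol` (default 1e−10 relative) every step.

### Stability

The critical explicit step is Δt_c = min_i 2B_i/(C_i + 4A_i/Δx_i²).  The
constant 4 is the worst-mode (θ = π) von Neumann bound of the
forward-time/centred-space scheme on a uniform unbranched chain.  The test
suite brackets this formula against an exact oracle — bisection on the
spectral radius of the assembled one-step update matrix (boundary
projection included, HH elements linearized at rest) — and finds agreement
within 2 % on unbranched chains whose critical elements sit in locally
uniform blocks, the regime the derivation assumes.  On branched trees the
chain-derived bound can exceed the true threshold by a few percent (a
branch point has three links, not two); `cabletree inspect` therefore
reports the oracle value alongside Δt_c, and production explicit runs use
η = 0.6–0.9.  Runs set Δt = η·Δt_c; the configuration layer rejects η > 1
for the explicit scheme and permits η ≫ 1 for the implicit one.

## Mechanical coupling

Loading is quasi-static: a macroscopic axial strain (with strain rate) is
mapped to a microscopic neurite strain by a registered transfer function
(identity by default — tissue-to-cell transfer models plug in here, and the
strain rate is carried through for their benefit), the geometry is rescaled
once before time stepping as Δx = Δx₀(1+ε), d = d₀/√(1+ε), and the solver
runs on the strained tree.  The d ∝ (1+ε)^{−1/2} exponent is the
incompressibility reading (d²Δx conserved exactly); the linear alternative
d = d₀/(1+ε) is isolated behind the same one-line function if a different
constitutive choice is wanted.  Stretch-induced channel damage (e.g. the
sodium-current left-shift) is exposed only as a hook: per-element overlays
scaling Ḡ_Na/Ḡ_K/G_L, offsetting E_Na/E_K, or shifting the potential seen
by the gating rates.  The damage law itself (and its calibration) is out
of scope; the geometry-only ε = 0.25 scenario reproduces the qualitative
deficit signature (later arrival, amplitude not higher) but deliberately
makes no quantitative damage claim.

## Parameter sets and scenarios

`classic_squid`: per-area values C = 1.0 µF/cm², Ḡ_Na = 120 mS/cm²,
Ḡ_K = 36 mS/cm², G_L = 0.3 mS/cm², ρ_a = 35.4 Ω·cm, V_rest = −65 mV,
E_Na = V_rest + 115 mV, E_K = V_rest − 12 mV, membrane thickness 10 nm;
myelin reuses the membrane constants per layer.  `mammalian_node` scales
the channel densities ×10, reflecting the order-of-magnitude higher
channel density of nodes of Ranvier.

The standard myelinated-axon scenario is 50 nodes (2 µm, HH) alternating
with 49 internodes (200 µm, CT, 20 × 10 nm myelin layers) on a 1 µm fibre
(9.9 mm total), stimulated with 0.5 nA for 0.1 ms at the first node;
probes sit at proximal/mid/distal nodes and a distal mid-internode.  With
single-element nodes (a standard compartmental choice) Δt_c ≈ 28 ns and
the AP travels at ≈ 2.3 m/s.  The published large-scale variant of this
scenario reports Δt_c = 13 ns; that value depends on an externally
published electrical/geometric parameter set that is not reproduced here,
so the bundled literature-typical preset does not match it — the
acceptance suite records this as an open red check rather than fitting the
geometry to the printed number.  The dendritic-tree scenario uses the
random symmetric builder (full binary tree, per-segment length jitter,
deterministic per seed); segmented reconstructions load through the SWC
adapter.

## Validation scaffolding

* **Analytic cable**: uniform passive cable with constant current I at one
  sealed end; steady state V(x) − V_rest = I·R_∞·cosh((L−x)/λ)/sinh(L/λ),
  λ = √(r̂_m/r̂_a), R_∞ = √(r̂_m r̂_a).  The benchmark cable carries mirror
  ghost elements at both ends so the zero-flux plane sits exactly at the
  physical boundary; at Δx = λ/50 the solver's steady profile matches to
  ~1e−3 % (L∞, normalized by the peak offset) and the observed spatial
  order on a Δx ladder is 2.0.  Backward Euler relaxation with Δt ≫ τ_m
  provides the steady state.
* **Metrics**: conduction velocity from linearly interpolated upward
  threshold crossings (default threshold V_rest + 20 mV — a fixed,
  configurable convention; the measurement convention of the original
  study is unstated); AP amplitude as max(V) − V_rest; convergence order
  as the least-squares slope of log error vs log step, with non-monotone
  or machine-noise ladders reported and no order claimed.

## What the synthetic scenarios do and do not show

The generators produce idealized geometry: perfectly cylindrical elements,
uniform myelin, noise-free parameters; the only randomness is structural
(tree jitter, chain composition).  Passing tests therefore demonstrate
numerical correctness (fixed points, stability bounds, convergence,
cross-scheme consistency and coupling directions), not biological fidelity
of any particular fibre: real axons differ in channel kinetics at nodes,
paranodal structure, and temperature (no Q10 correction is modelled).
Conduction velocities are meaningful as relative quantities (e.g. strict
growth with fibre diameter), not as predictions for a specific species.

## Problem sizes and numerical choices

Test and acceptance runs use reduced scales chosen as the smallest
configurations that exhibit each phenomenon cleanly: 10 mm / ~1030-element
axons for propagation and strain (5–8.5 ms simulated), ≤100-element chains
for the stability oracle (dense eigenvalues are exact there), λ/10–λ/80
cables for convergence.  Explicit runs detect divergence (non-finite V)
every step and abort with the offending element; stepping above Δt_c warns
but is permitted, matching the exploratory use of the bound.  Probe traces
are decimated to at most ~1e5 samples per run by default.  All
floating-point output is written with 17 significant digits so CSV round
trips are bit-exact.

## Known limitations

No soma compartment, synapses, or network coupling; one HH channel pair
(no alternative channel models); no temperature dependence; quasi-static
loading only (no time-varying strain during a run); the damage law behind
the channel-alteration hook is not included.  The implicit scheme's
semi-implicit linearization is first-order in Δt for active membranes — at
η = 100 the explicit and implicit traces differ by a few percent of the AP
amplitude near the upstroke (arrival times still agree to <1 %); refining
to η = 10 brings the traces within 0.3 %.
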
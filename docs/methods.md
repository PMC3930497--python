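# Methods

`plectosim` simulates a magnetic-tweezers experiment on a single DNA
molecule with constrained rigid-body Langevin dynamics, the way a physics
engine integrates articulated bodies: no bond potentials, but hard
kinematic constraints solved at the velocity level each step.

## Model

DNA is a serial chain of N rigid cylinders, each of length b = 3.4 nm
(10 base pairs, one double-helix pitch) and effective radius
r_eff = r_cryst + λ_D, where λ_D = 0.304 nm/√(c [M]) is the Debye length of
the monovalent buffer and r_cryst = 1 nm; at 100 mM this gives
r_eff ≈ 1.96 nm. Internally everything is in reduced units b = m = k_BT = 1,
so the time unit is τ = b√(m/k_BT) (≈ 1.7×10⁻¹⁰ s for a 650 Da/bp cylinder
mass at 300 K), the force unit k_BT/b ≈ 1.22 pN and the torque unit k_BT.

Consecutive cylinders are connected by ball-and-socket joints at their
shared endpoints. The first cylinder is welded to the anchoring plane z = 0
and the last is welded to a spherical bead; both end cylinders lie tangent
to their attachment surfaces. The bead is driven in one of three modes:
constant +z force with free rotation (force clamp), prescribed rotation
about z with x/y locked (turn clamp), or constant z-torque with x/y locked
(torque clamp).

### Constrained dynamics

Body states are (x, q, v, ω) with unit quaternions and world-frame angular
velocities. Each step, the holonomic constraints C(x, q) = 0 (3 rows per
ball joint, 6 per weld, 2–3 per bead clamp, 1 per contact) are enforced
through Lagrange multipliers λ solving

    A λ = rhs,   A = J W⁻¹ Jᵀ + diag(cfm)/Δt,
    rhs = k/Δt − (erp/Δt²) C − (1/Δt) J (u + Δt W⁻¹ F_ext),

so that the post-step generalized velocity satisfies
J u′ = k − (erp/Δt) C − cfm λ (k is the drive velocity of clamped rows,
zero elsewhere). The error-reduction parameter erp = 0.8 removes 80% of any
bearing separation per step; the constraint-force mixing cfm = 10⁻¹⁰ makes
A strictly positive definite (an implicit, energy-free spring-damper).
λ carries force units and the constraint force is F_c = Jᵀλ.

Three solvers are used, dispatched exactly as in the step loop:

* **exact (banded)** — for the contact-free serial chain A is block
  tridiagonal (the constraint graph is a path: plane–chain–bead–magnet), so
  a banded Cholesky factorization solves it exactly in O(N);
* **projected SOR** (ω = 1.3, 60 sweeps) — when contacts add unilateral
  rows (λ ≥ 0); accepted iff the predicted bearing-separation growth
  Δt²·max|Aλ − rhs| (complementarity-aware) stays below 10⁻⁶ b;
* **active-set direct** — Cholesky on the working set with principal-pivot
  style updates; always converges for SPD A and serves as the SOR fallback.

Integration is semi-implicit Euler: velocities first (from external,
elastic, gyroscopic −ω×(Iω), thermostat and constraint forces), then
x += Δt v and q ← exp(½ωΔt) q (exponential map, renormalized). The default
Δt = 0.000592 τ. The scheme is dissipative-stable, not time-reversible;
without a thermostat, total energy drifts < 1% over 10⁴ steps.

### Collisions

Capsules (spherocylinders) approximate the cylinders for collision geometry;
inertia uses the solid-cylinder formulas. A uniform spatial hash grid
(cell = largest contact reach) proposes pairs; the narrow phase computes
segment–segment closest approach and emits one contact joint per
overlapping pair (midpoint, common normal, depth), with restitution 0 and
no friction. Contacts of the chain with the plane and the bead are included;
the first cylinder/plane and last cylinder/bead pairs are permanently
attached and excluded. Because capsule caps reach r beyond each joint,
chain neighbours with |i−j| ≤ ⌊2r/b⌋+1 would overlap even in a straight
chain; these pairs are excluded from collision, and steric protection at
those arc separations is carried by the bending rigidity instead. This is
a consequence of the capsule choice — flat-ended cylinders would not need
it — and matters only below distances the elastic energy already forbids.

### Elasticity

Adjacent triads (t, u, t×u) interact through

    E = g_b (1 − cos θ) + g_t (1 − cos φ),

with θ the bending angle between tangents and φ the ZXZ twist
(atan2 form, well defined except at θ = π, where the twist torque is
switched off for the step — configurations that are elastically
unreachable at DNA-like rigidities). Torques are the exact rotational
gradients of E, equal and opposite on the two bodies. With this energy the
per-joint tangent correlation is exactly the Langevin function
L(g) = coth g − 1/g, so rigidities calibrate against persistence lengths
through exp(−b/l) = L(g) (bracketed root-find, tolerance 1e-10, exact
inverse available). For l_p = 50 nm this gives g_b ≈ 15.2 k_BT; for
l_t = 95 nm, g_t ≈ 28.4 k_BT — the printed value of the twisting rigidity
constant, which pins the convention: a ½gθ² energy with the naive g = l/b
calibration would give 27.9 instead. Per-joint twists are unwrapped
cumulatively (|Δφ| < π per step is guaranteed by the timestep), giving
Tw = Σφᵢ/2π.

### Thermostats

*Local*: per-body friction −γMv, −γIω plus Gaussian noise of per-component
variance 2γ k_BT M/Δt generated along the principal axes and rotated to the
world frame (exact fluctuation–dissipation pairing). γ = 10/τ by default.
The semi-implicit map contracts velocities by exactly (1 − γΔt) per step.

*Global*: stochastic velocity rescaling extended to rotational degrees of
freedom. Each step the updated velocities are rescaled by the closed-form
factor α(K; n_dof, k_BT, γΔt) that realizes the exact
Ornstein–Uhlenbeck update of the kinetic energy K over Δt; the equivalent
generalized force ((α−1)/Δt)Wu is an exact scalar multiple of the momentum
P = Wu, hence J W⁻¹F_glob ∝ J u = 0 on the constraint manifold: the
thermostat never disturbs the constraint forces. Stationary K follows the
Gamma(n_dof/2, k_BT) law at any Δt. n_dof counts permanent joints only
(6N − m); intermittent contacts are not counted. Because a rescaling
thermostat cannot heat a cold start, the driver draws Maxwell–Boltzmann
initial velocities (the first constraint solve projects them).

Sampling acceleration is quantified by an ensemble quench: replicas of a
free N = 50 chain start straight and the time for the ensemble-mean
end-to-end distance to cover half the gap to its equilibrium value (known
exactly from Boltzmann draws, below) is compared between thermostats. At
N = 50 the global thermostat halves the gap in ~3 τ while local Langevin
has not reached the half-gap after 40 τ — an order of magnitude at desk
scale, growing with system size. Stationary-autocorrelation fits of the
same quantity are far noisier at affordable run lengths and are not used
for this comparison.

One caveat governs when the global thermostat is appropriate: it controls
only the total kinetic energy, so energy sharing between weakly coupled
groups of degrees of freedom relies on the Hamiltonian coupling. With the
twist rigidity switched off (the ideal freely-jointed and bending-only
chains), the axial spins of the cylinders are almost decoupled and the
system is near-integrable: mode temperatures then equilibrate extremely
slowly and configurational averages acquire long-lived biases. The
DNA-parameter chain (g_b, g_t > 0, collisions) is far from this limit.
Ideal-chain reference comparisons therefore use the local thermostat,
which thermalizes every degree of freedom directly.

## Protocols and observables

Force-extension, hat-curve (turn clamp, ramped at 0.05 turns per 10³ steps
by default, then held) and torque-clamp protocols return tidy DataFrames
with autocorrelation-corrected standard errors (Sokal-style integrated
autocorrelation time). Extension is the height of the chain end above the
anchor plane, relative to L₀ = N b. Overtwist is σ = n/Lk₀ (turn clamp)
or the cumulative bead angle /(2π Lk₀) (torque clamp), with Lk₀ = N.

Writhe uses the exact per-segment-pair Gauss solid-angle formula with a
two-ray closure (straight rays along −z below the anchor and +z above the
bead), the virtual circuit through the magnets that defines ΔLk in a
tweezers geometry; with both ends torsionally clamped, n = ΔTw + ΔWr holds
frame by frame. Reference curves: freely-jointed chain z/L₀ = L(f b/k_BT)
and the seven-coefficient worm-like-chain interpolation formula (numerically
inverted for extension-at-force).

Supercoil geometry: the hat-curve slope is related to the plectoneme
radius and angle by q = −ρ(f)·4πR/sin 2α (writhe density sin 2α/(4πR) of
an interwound superhelix; ρ is the extended-phase relative extension). A
scalar slope cannot determine both R and α, so the inverse recovers one
given the other; (R, α) are estimated independently from simulated
configurations via close, nearly antiparallel segment pairs (R = half the
mean inter-axis distance, α = half the mean deviation of the crossing angle
from π) — a constructed estimator, not a published recipe. The plectonemic
torque law is fitted as Γ = 2π k_BT (ξ_p/p)(σ − σ*). The buckling torque is
located at the maximum of Var(σ) across a torque sweep, with a two-state
(two-means) decomposition of the extension series for dwell statistics.

## Initialization and replica sampling

Force-extension runs start from a direct Boltzmann draw of the chain under
tension: tangents Gibbs-sampled with their exact von Mises–Fisher
conditionals (field g_b(t_{i−1}+t_{i+1}) + f b ẑ; without tension the
one-pass transfer sampling is already exact and no sweeps are needed),
twists von Mises, frames parallel-transported. The jointed-rigid-body
chain's configurational equilibrium is exactly this product-measure
ensemble — constrained Hamiltonian dynamics samples e^(−βV) δ(C) with
respect to the parent Liouville measure, and integrating the momenta
cancels the mass-metric determinant against the constraint surface
measure — so the draw is a true equilibrium sample, not just a warm start.

Because conformational modes relax slowly (bending-mode rates fall off as
q⁴; collective swing under tension is a long-period pendulum), time
averages from a single trajectory carry few effective samples and their
autocorrelation-corrected errors are unreliable at desk scale. Reference
comparisons (FJC/WLC curves, persistence-length fits) therefore average
over many independent replicas, each freshly drawn, briefly equilibrated
and sampled; standard errors come from the replica spread, which is immune
to intra-trajectory correlation. Turn- and torque-clamp runs instead start
from the assembled straight state so that the twist bookkeeping has a
clean Tw = 0 reference.

## What the tests show (and what they do not)

The validation suite runs at desk scale: chains of 30–128 cylinders and
10⁵–10⁶ steps per condition, i.e. one to two orders of magnitude below a
3-kb molecule (N = 300) mapped over experimental acquisition times.
Closed-form limits (FJC, WLC, equipartition, Gamma-law kinetic energy,
White's theorem, solver equivalences) are sharp at this scale. Two caveats:

* finite-size boundary effects on force-extension are at the percent level
  for N = 50 and partially offset the rigid-ensemble stiffening seen at
  small N; agreement with the continuum WLC formula within a few percent is
  the realistic expectation, not exactness;
* near buckling, desk-scale torque-clamp series exhibit the two coexisting
  branches and their anticorrelation, but not many independent equilibrium
  switching events — dwell statistics at this scale characterize branch
  occupancy during extended sampling, not fully converged two-state
  kinetics.

Known limitations: no sequence dependence, no denaturation or overstretched
forms (quadratic-in-cos elasticity only), single-contact manifolds, no
hydrodynamic interactions (thermostat friction is body-local), and bead
inertia deliberately reduced (a sampling choice; equilibrium observables
are inertia-independent).
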
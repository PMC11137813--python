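# Methods

This note records the models, numerical choices and limitations behind
`coordff`, in the order the pipeline uses them.

## Pair potentials and conventions

The coordination bond between the heme iron and a gas-ligand atom is a
single pair-specific Lennard-Jones term. Parameter tables in this area
print "ε, σ" without stating the functional form, so both conventions are
supported and every object carries its convention explicitly:

* sigma-form (default): U(r) = 4|ε| [(σ/r)¹² − (σ/r)⁶], minimum −|ε| at
  2^(1/6) σ;
* R_min-form (CHARMM NBFIX native): U(r) = |ε| [(R/r)¹² − 2(R/r)⁶],
  minimum at R.

ε is stored signed (negative = attractive, matching printed tables); all
formulas use |ε|; ε = 0 encodes a zeroed (disabled) pair. Units are
kcal/mol, Å and fs throughout; forces are kcal/mol/Å with an optional
display conversion 1 kcal/mol/Å ≈ 69.48 pN. Nonbonded terms are smoothly
switched off between 8 and 10 Å with the standard cubic-in-r² switching
polynomial (the named algorithm does not fix the polynomial; this is the
common choice). At the distances this system explores the switch is
almost always identity, but it is applied for protocol fidelity.

## The tabulated-force rule and fit consistency

Reference curves arrive as energy tables on a uniform 0.1 Å grid. The
force table is the adjacent difference F_i = −(U_{i+1} − U_i)/Δr assigned
to the left grid point; the output has one fewer usable point. A single
interval with a larger energy step than its neighbours produces a local
spike in F — a property of the scheme that is deliberately preserved
(and can be masked in the fit via a per-point mask).

Because a forward difference is midpoint-accurate, comparing it against
an *analytic* derivative at the left grid point carries an O(Δr) bias —
about 5% in the recovered ε and 2% in σ at this grid spacing, which a
roundtrip (synthesize → difference → fit) cannot tolerate. The fit
therefore supports two residual models: `analytic` (the literal formula)
and `fd`, in which the model force is the same adjacent difference of the
model *energy* on the same grid. Roundtrips through the difference rule
use `fd` and recover generating parameters to machine precision; fitting
externally supplied force data uses `analytic`.

The least-squares fit itself exploits that the LJ force is linear in |ε|:
the depth is profiled out in closed form and the problem reduces to a
bounded 1-D search over σ (coarse bracket on [0.7, 4.8] Å, golden-section
refinement, final trust-region polish). This removes the repulsive-wall
local minimum that plagues naive 2-parameter starts. Non-convergence is
flagged in the result, never silent. The fit window defaults to
1.75–2.95 Å and points outside it are ignored entirely; residuals are
unweighted by default.

## The reduced complex

All dynamics run on a reduced FePI(GL) model: Fe at the origin, four
pyrrole nitrogens in-plane at 2.0 Å, an imidazole nitrogen at 2.1 Å below
the plane, and rigid diatomic ligands (C≡O 1.128 Å, O=O 1.21 Å) above the
plane — on the same side when CO and O₂ are both present. The heme frame
and imidazole are held fixed; only ligand atoms move. These internal
coordinates are plausible placeholders from typical heme coordination
geometry, not a reproduction of any specific optimized structure.

Interactions: the coordination LJ pairs (Fe–C of CO, Fe–O¹, Fe–O²),
plus purely repulsive WCA sterics (cut-and-shifted LJ, ε = 0.05 kcal/mol,
σ = 2.9 Å → contact ≈ 3.26 Å, standard heavy-atom van-der-Waals values)
between atoms of different ligands, between ligand atoms and the
heme/imidazole nitrogens, and between Fe and the CO oxygen. The sterics
are the minimal ingredient that transmits the CO–O₂ competition and keeps
ligands on the bonding side of the plane. No electrostatics, no solvent,
no protein matrix.

The reference coordination parameters shipped as defaults are the
published two-site set: Fe–C(CO) (−21.49, 1.79), Fe–O¹ (−4.37, 2.74),
Fe–O² (−6.55, 1.90) (kcal/mol, Å, sigma-form as printed).

What the stand-in does *not* capture: solvent friction and dielectric
screening, the heme pocket's steric funnel, porphyrin flexibility, spin
physics and charge transfer. Consequently absolute peak forces and free
energies are properties of the reduced model; only trends, ratios and
the fit/inversion machinery itself are meaningful points of comparison
with the solvated-protein numbers.

## Dynamics engine

A BAOAB Langevin integrator (2 fs step, 300 K, friction 5 ps⁻¹ — a
standard implicit-environment value; both configurable) with exact
two-body constraint projection for the rigid diatomics (the single-bond
analogue of SHAKE/RATTLE, exact for a diatomic, so bond lengths never
drift). Site masses are atomic masses. The thermostat holds the measured
kinetic temperature within ~3% of target at 2 fs. Energy terms are
pluggable (pair table, collective-variable biases, metadynamics bias,
arbitrary callables), which is how the same engine drives equilibrium
runs, steered pulls, metadynamics and the toy-landscape oracles in the
tests. T = 0 disables the noise and gives deterministic damped dynamics.
Identical seeds give bitwise-identical trajectories on one platform.

Energy scans evaluate the step-0 potential energy of the complex with the
ligand rigidly translated along the out-of-plane axis — no dynamics —
and flag (NaN) any grid point that would overlap sites.

## Featurization for inverse design

Each database record (ε₁, σ₁, ε₂, σ₂) — magnitudes during sampling,
converted to the signed convention at the physics boundary — is reduced
to three features:

* **mean Fe–O²–O¹ angle.** Default ("scan"/reduced-cost) mode computes
  the Boltzmann average of the rigid-rotor configuration integral of O₂
  above the fixed heme at 300 K by quadrature over (r, θ): energy
  LJ₂(r) + LJ₁(d₁(r, θ)) + axial steric background + distal-atom steric
  background (distal atom tilted between two heme nitrogens), weight
  r² sin θ, grid r ∈ [1.7, 3.5] Å × θ ∈ [5°, 175°]. The upper r bound
  restricts the average to the bound state, which is what a 20 ps
  equilibrium run samples. The "md" mode runs the actual 20 ps /
  100-snapshot Langevin protocol; the two agree to within a few degrees
  (tested), and the quadrature is used for database-scale featurization
  because it is deterministic and ~10³× faster.
* **ε_f, σ_f.** An energy scan of the two-site complex on the 0.1 Å fit
  grid, at the *relaxed* (minimum-energy) tilt of the quadrature energy —
  matching the convention of rigidly translating an optimized geometry —
  followed by the adjacent-difference rule and the fd-consistent
  effective single-LJ fit. Records whose effective fit fails to converge
  are excluded with a logged count (none occur at the default settings).

Sampling of the database is uniform rejection sampling inside the
constrained box (sum, ratio and σ ranges), seeded and reproducible.

## The feedforward network

scikit-learn's MLPRegressor with the stated architecture: hidden layers
(64, 64, 64), ReLU, adam at learning rate 5·10⁻⁴, 2001 epochs, MSE loss,
no regularization, minibatch size 200 (the batching is not specified by
the protocol; 200 is a conventional choice at this data size). Features
and targets are z-scored with statistics stored in the model; the
serialized model is a self-contained JSON document (architecture,
weights, normalization, feature bounding box, RMSEs). An 80/20 split of
the 12,000-record database gives 9,600 / 2,400; per-output RMSEs are
reported on both partitions. Train and test RMSEs agree closely (no
overfit); the distal-oxygen parameters carry several-fold larger RMSE
than the proximal ones because three features cannot fully determine four
parameters — the distal share is the weakly identified direction.

Inversion is a single forward pass. A target outside the axis-aligned
bounding box of the training features is flagged as extrapolation.

**Known limitation.** The published two-site O₂ parameter set has depth
ratio ε₁/ε₂ ≈ 0.667, outside the sampled 0.3–0.6 range. Feeding its
features back through the network is therefore an off-manifold query: the
network, a conditional-mean regressor on the constrained training region,
returns the proximal depth biased high by ≈ 0.3 kcal/mol (≈ 4.5%) —
stable across training seeds and ≈ 2× its on-manifold test RMSE — while
the proximal σ and the distal σ are recovered to well under 1%. The
corresponding acceptance test asserts the stricter on-manifold tolerance
and is expected to fail on that one sub-assertion; the bias is structural
(no training choice removes it) and is reported rather than papered over.

## Steered pulls and the restrained-O₂ environment

Protocol per run: build the CO (+O₂) complex; relax 20 ps under an upper
wall on Fe–C (ceiling 1.89 Å, κ = 150 kcal/mol/Å²) and, when O₂ is
present, the zero-reference harmonic on Fe–O² at the sweep stiffness;
then drop the wall and pull Fe–C with a moving harmonic (κ = 10
kcal/mol/Å², reference growing from the instantaneous distance). The
recorded pulling force is the spring force κ(r₀(t) − d). Stiffness 0 is
the control without an O₂ molecule.

Desk runs scale the nominal 1 Å/ns rate by a single factor (default 50,
logged and reported); rupture force is rate-dependent, so the
stiffness-0 and stiffness-3 runs are always compared at the same rate and
only their ratio is quoted. The peak is taken from a 1 ps running mean of
the force trace (the raw spring force carries thermal noise of several
kcal/mol/Å); the restrained-O₂ distance is the time mean of Fe–O² over
the CO-bound (pre-peak) part of the pull, averaged over replicates.
Replicates use seeds seed, seed+1, …, seed+4 (n = 5).

At the defaults the restrained O₂ at stiffness 3 hovers ≈ 2.6 Å from the
iron — it cannot reach its pair minimum (2.13 Å) because the bound CO
occupies the axis and the heme nitrogens exclude the flanks — and the
mean peak force drops to ≈ 40–45% of the control: the restraint presses
the O₂ into the departing CO and the freed axial site is immediately
stabilized by O₂ binding. The T → 0 quasi-static limit of the same
machinery (sterics off) reproduces the analytic maximum attractive LJ
force (26/7)^(1/6)-point value to 0.01%, which pins down the pulling
machinery independently of the thermal physics.

## Well-tempered metadynamics

Gaussians on the (Fe–C, Fe–O²) distance pair: initial height 8 kcal/mol,
width 0.2 Å, one hill per ps, both CVs confined by 5 Å / 150 kcal/mol/Å²
upper walls so ligands rebind rapidly. Heights decay as
h = h₀ exp(−V(s)/kᵦΔT) with ΔT = (γ−1)T; the bias factor γ is not part of
the published protocol and defaults to 10, configurable and reported in
all outputs. The free energy is F(s) = −γ/(γ−1)·V_bias(s) on a regular
grid, minimum-shifted to zero. On analytic toy landscapes (flat line,
3 kcal/mol double well) the reconstruction is accurate to < 0.5 kcal/mol
RMS within a few hundred ps — the resolution of the estimate at these
hill parameters; convergence on the molecular system is assessed by slice
values stabilizing between hill-count checkpoints.

The *effective bond energy* of a constant-Fe–O² slice is the maximum free
energy between the slice's bond-length minimum and the outer grid edge,
relative to that minimum (gauge-invariant; a slice whose minimum sits on
the outer edge has no bound state and is flagged). At 500 ps the slices
reproduce the competitive-binding picture: the effective CO bond energy
collapses from ≈ 15 kcal/mol at Fe–O² ≈ 3.8 Å to ≈ 0 at 2.1 Å, i.e. the
CO bond exists only while the O₂ is kept away from the iron.

The approach-pattern analysis reports, per frame, the O²–Fe distance and
the minimum O²–N(heme) distance, plus the fraction of close frames
(Fe distance < 3.5 Å) in which O² is nearer the iron than any nitrogen —
direct axial approach versus sliding over the plane.

## Problem sizes used by the shipped runs

Database 12,000 records (quadrature featurization); network 2001 epochs;
pulls: 20 ps relaxation + pulls at 50 Å/ns over 4 Å of extension, 5
replicates per stiffness; metadynamics 500 ps (500 hills). These are the
package's default desk-scale settings; every routine accepts longer
durations and slower rates through its arguments or the JSON run config.
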
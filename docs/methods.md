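# Methods

This note records the models, numerical choices and known limitations behind
`latticeimplant`, in the order the pipeline runs them.

## Unit-cell morphology

The octet-truss cell on a cubic tile of edge *l* consists of six face-centre
nodes forming an octahedral core (12 struts) plus 24 corner struts forming
the corner tetrahedra; every strut has length a = l/√2. With circular struts
of radius *t*, first-order bookkeeping (12 interior + 24 half-shared face
struts) gives the classical closed form

    rho = 6·√2·π·(t/a)².

Two points deserve emphasis:

* **The formula's *l* is the strut length.** `density_from_strut(t, l)`
  documents its second argument as the strut length; `UnitCellSpec` stores
  the cell edge and converts. Treating the cell edge as the formula's length
  scale would understate the strut volume by a factor of two.
* **The closed form is first-order only.** It ignores the material shared
  where struts meet. At nominal ρ = 0.5 the true union volume of the
  wireframe is ≈ 0.36 of the cell (Monte-Carlo and converged voxel counts
  agree); at ρ = 0.05 the formula is good to better than 10%. Throughout
  the pipeline the *nominal* ρ is the design variable — it indexes the
  homogenization sweep, the surrogate and the optimizer consistently — and
  the geometric gap is a property of the cell family, not an error that
  accumulates. The lattice builder's volume bookkeeping is therefore checked
  against Monte-Carlo union oracles, not against Σρ_e·V_e.

The design window combines a manufacturing floor (printable strut thickness,
default 0.2 mm, interpreted as a **diameter**; `strut_size_is_diameter`
switches to radius) with a clinical ceiling on the pore opening
(p = l/√2 − 2t ≤ 0.8 mm for bone ingrowth; the pore-opening formula is this
package's definition — the face-diagonal gap between parallel strut
surfaces). Both constraints exclude *low* densities, so the admissible
interval for cell edges 1.2–1.5 mm is a sub-interval of the global density
bounds [0.2, 0.7]. The optimizer's bounds follow the density (not porosity)
reading of those limits.

## Homogenization

The RVE is one unit cell voxelized at n³ (default 48) with periodic wrap;
a voxel is solid when its centre lies within *t* of a strut axis. With
`antialias=True` (the sweep default) the signed distance is converted to a
per-voxel solid fraction over a one-voxel ramp and that fraction grades the
voxel stiffness; this removes the staircase dependence of thin struts on the
grid, which otherwise makes E(ρ) non-monotone at coarse resolutions (two
neighbouring nominal densities can voxelize to the same binary grid).

Each of the six unit test strains is imposed as an element-local affine
displacement; the periodic fluctuation solves K w = f on trilinear hexes
(2×2×2 Gauss) with void voxels retained at an ersatz stiffness of 10⁻⁹·Es.
The effective stiffness is assembled from mutual strain energies, which
keeps C symmetric and energy-consistent by construction; a dual route via
volume-averaged stresses (exactly equal by Hill's lemma) is used as a test
oracle and as the fast path below.

**Linear solver.** Conjugate gradients preconditioned by the *exact inverse
of a homogeneous reference operator*: under periodic boundary conditions the
reference stiffness is block-circulant, so its inverse is applied per
Fourier mode (3×3 blocks) with FFTs. Iteration counts are nearly resolution
independent and a 48³ cell problem solves in seconds on one core; relative
residual tolerance 1e-8. The rigid-translation mode is projected out via
the zero-frequency block.

**Cubic shortcut.** The voxelized octet indicator is exactly invariant under
the cubic point group, so C has three independent constants; one normal and
one shear load case determine them via average stresses. `density_sweep`
exposes this (`exploit_cubic_symmetry`), cutting the sweep cost threefold;
tests verify the shortcut against the full six-case solution to 1e-6.

A kinematically uniform (affine Dirichlet) option exists for comparison and
upper-bounds the periodic estimate, as theory requires.

**Convergence.** The voxel discretization converges slowly in absolute
terms: the axial modulus at ρ = 0.5 still drifts ~10–15% between grid
halvings around n = 16–48. The *shape* of E(ρ) — what the surrogate needs —
is far more stable: the polynomial fit quality is ≥ 0.998 R² at n = 48.
Figures from body-fitted meshes of the same cell will not be matched
digit-for-digit by a voxel scheme at these resolutions.

## Surrogate

Least squares of the stated degrees (2 for Ē/Es, 3 for ν̄/νs) on the sweep;
R² = 1 − SS_res/SS_tot. The fitted domain is the sampled range [0.1, 0.8];
the optimizer only queries [0.2, 0.7], so extrapolation never occurs in the
pipeline. Outside queries clamp with a logged warning (the quadratic exceeds
the solid modulus before ρ = 1, so extrapolation is unsafe); clamping can be
disabled to make such queries raise. The macro model treats (Ē(ρ), ν̄(ρ)) as
an isotropic pair — a deliberate simplification: the octet cell is cubic,
not isotropic, but the two scalar constants are what the surrogate provides,
and the same pair is used consistently in optimization and stress recovery.

Reference coefficients (1.23, −0.2411, 0.03213; 0.7165, −0.7995, −0.05101,
1.134), as reported for titanium octet lattices in the graded-implant
literature, ship as a sweep-free default and as a fixture for tests.

## Bone material

The HU→modulus law is implemented exactly as printed, including its
discontinuity at HU = 1500 (the cancellous branch reaches 2713·2^2.36 ≈
13.9 GPa just below the cortical 17 GPa plateau) and the tie-breaks at the
overlapping breakpoints (outer branches win). Element HU is the mean over
voxels in the element's bounding box, falling back to the nearest voxel for
sub-voxel elements; an optional bin count quantizes the field into discrete
materials. Poisson's ratio is 0.3 for all bone.

## Macro FE

Linear 8-node hexahedra with full 2×2×2 quadrature, mm–N–MPa units,
direct sparse factorization (meshes in this package are ≤ ~10⁴ dofs), and a
1e-8 residual guard. Per-element strain energies Δc_e = u_eᵀk̄_eu_e sum to
the compliance identically; von Mises stress is evaluated at centroids.
Resultant loads are spread over named node sets proportionally to tributary
boundary-face area (equal weights as fallback). Quadratic elements, contact
and geometric nonlinearity are out of scope; implant–bone interfaces in the
assembly fixture are bonded (shared nodes).

## Genetic algorithm

One gene (8 bits, linear quantization of [0.2, 0.7]) per element; the mesh
is the population and evolves in place. Per generation: FE solve → fitness
Δc_e → mate selection by roulette over element fitness → uniform crossover
(each bit from the mate with probability 0.3) → directional mutation (with
probability 0.2 an element sets a random 0-bit if its fitness is at/above
the median, else clears a random 1-bit) → multiplicative rescaling toward
the lower bound until the re-quantized mean meets V₀ = 0.4. Convergence is
declared after five consecutive generations with |c_k − c_{k−1}|/c₁ < 10⁻³
(a single quiet generation is routine mutation noise); the best feasible
design seen is returned (elitism), so the result can never be worse than
the uniform initial design.

**Operator wiring.** The crossover "father" is the element's **own** gene;
only the mate is fitness-selected (`GAConfig.parent_mode="self"`; the
variant with both parents selected is available as `"roulette"`). The
reason is disruptiveness: replacing every element's gene by recombined
genes of globally selected elements each generation destroys the spatial
density pattern faster than selection can rebuild it. On an extruded
MBB-like beam benchmark against an optimality-criteria reference (same FE,
same material law, same volume), measured best-compliance ratios are:
both-parents roulette ≈ 1.9× OC, self-father ≈ 1.7×, crossover disabled
(pure directional mutation) ≈ 1.15×. The shipped default keeps the
crossover factor at 0.3; users who want the strongest optimizer should set
`crossover_factor=0`, which degenerates cleanly to a stochastic
evolutionary-structural search. These figures are asserted in the test
suite at conservative bounds (2.0× for the default, 1.3× crossover-free).

Sensitivity fidelity: element energies rank brute-force compliance changes
under single-element density reduction with Spearman ρ ≈ 0.95 on an
8-element oracle.

A `design_mask` restricts evolution to a subset of elements (the implant)
while the rest keep fixed materials (bone) — used by the bonded cage+bone
assembly fixture.

## Lattice builder

Each macro element maps one unit cell through the trilinear transform of
the unit cube (elements are assumed roughly cubic; curved elements are
approximated by their trilinear image). Strut radius realizes the element's
density at the element's effective edge (volume^(1/3)). Coincident nodes
merge at 1e-6 of the mean cell edge; struts shared by neighbours dedupe
keeping the larger radius — adjacent cells of different density thus join
with the conservative (thicker) strut. The printable surface is the
marching-cubes isosurface of the voxel union of all strut cylinders
(boolean union by construction), oriented outward and checked watertight
before STL export. Fat junctions can create more surface handles than the
strut graph has cycles, so topology checks bound the genus from below
rather than pinning it.

## Fixtures

* **Phantom**: nested spheres (marrow core 50 HU, cancellous 600 HU,
  cortical shell 1800 HU, air −1000 HU) at radii fractions (0.22, 0.35,
  0.45) of a 40³ mm volume, plus seeded Gaussian noise of 25 HU — large
  enough to exercise all three branches, small enough (≥ 10σ from the
  thresholds) that pure-region labels stay recoverable.
* **Cage**: a gnomonic square patch projected onto a sphere (outer radius
  28 mm, 3 mm shell) with two flange strips continued toward the equator,
  flange ends fixed, and the hip resultant (−408, 1919, 0) N — 250% of an
  80 kg body weight, magnitude 1962 N — spread over the inner socket nodes
  by tributary area. The **assembly** variant bonds the cage to a
  cancellous (600 MPa, 3 mm) and cortical (17 GPa, 3 mm) backing; this is
  what makes stress-shielding comparisons meaningful, since a lone shell's
  stress state is statically determined and insensitive to its own
  stiffness.
* **Cantilever**: unit-cube hexes, one face clamped, far edge (or centre
  node) loaded; the 20×10×4 instance is the optimization benchmark and the
  40×4×4 instance the beam-theory check (tip deflection within 4% of
  Euler–Bernoulli).

All generators are pure functions of their spec and seed.

What passing on these fixtures does **not** show: anatomical pelvis
geometry, screw fixation, cement/liner contact mechanics, fatigue, or the
absolute stress magnitudes of a real cage — the fixtures probe orderings,
identities and constraint satisfaction, not patient-specific values. On the
synthetic assembly the solid cage produces the highest cage-side interface
stress and shields the bone (lowest bone-side stress); the compliance-
optimal graded design concentrates stiffness along the interface load path
and sits between the uniform lattice and the solid cage there. A claimed
interface-stress advantage of graded over uniform designs is geometry
dependent and is not reproduced on this fixture.

## Problem sizes and tolerances

Default production sizes: homogenization at 48³ (sweep of eight densities,
~3 minutes on one core via the cubic shortcut), GA on 800 elements for ≤ 80
generations (~20 s). The test suite uses 8³–32³ grids and ≤ 800-element
meshes. Key tolerances: CG relative residual 1e-8; FE residual guard 1e-8;
compliance/energy identities asserted at 1e-8 relative; cubic-symmetry
deviations ≤ 2%; surrogate R² ≥ 0.998 at production resolution. Degenerate
inputs (empty RVEs, disconnected phases, underconstrained meshes, empty
lattices, out-of-extent elements) raise typed errors naming the offending
axis or elements.
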
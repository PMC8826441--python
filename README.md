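# latticeimplant

Design toolkit for **functionally graded octet-truss lattice implants**,
built around the workflow used for porous acetabular reinforcement cages
(Burch–Schneider type) in revision hip arthroplasty: replace the solid metal
shell by a lattice whose relative density varies element by element, so the
implant's stiffness approaches that of the host bone, reducing stress
shielding while keeping pores open for bone ingrowth.

It is aimed at computational biomechanics and design-optimization
researchers who want a self-contained, scriptable version of this pipeline —
every stage runs on synthetic fixtures, no CT data or commercial FE/CAD
software required.

## What it computes

1. **Unit-cell homogenization** (`homogenization`). The octet-truss cell
   (octahedral core + corner tetrahedra; ρ = 6√2·π·(t/a)² with strut radius
   *t* and strut length *a*) is voxelized and six unit-test-strain cell
   problems ε⁰⁽ᵐ⁾ are solved with periodic boundary conditions on a voxel FE
   model; the effective stiffness follows from the mutual strain energies

   E^H_ijkl = (1/|Y|) ∫_Ys (ε⁰_pq − ε_pq) E_pqrs (ε⁰_rs − ε_rs) dY.

   Engineering constants come from the orthotropic compliance S = (E^H)⁻¹.
2. **Density–property surrogate** (`surrogate`). Quadratic/cubic polynomial
   fits Ē(ρ)/Es = a₂ρ² + a₁ρ + a₀ and ν̄(ρ)/νs = b₃ρ³ + b₂ρ² + b₁ρ + b₀ over
   ρ ∈ [0.1, 0.8], with R² reported for both.
3. **CT-to-bone materials** (`bone_material`). Hounsfield values map to
   apparent density ρ₀ = (HU/1500)·2.0 g/cm³ and a piecewise modulus law
   (cortical ≥ 1500 HU → 17 GPa; 100–1500 HU → 2713·ρ₀^2.36 MPa; ≤ 100 HU →
   20 MPa), assigned per macro element.
4. **GA compliance minimization** (`ga_optimizer`, `fe_solver`). Each hex
   element's density is a binary-coded gene; fitness is the element strain
   energy Δc_e = u_eᵀ k̄_e u_e; fitness-proportional mate selection, uniform
   crossover (factor 0.3) and directional mutation (factor 0.2) evolve the
   field, minimizing c = UᵀKU subject to V(ρ) ≤ 0.4 and 0.2 ≤ ρ_e ≤ 0.7,
   starting from the uniform feasible design.
5. **Graded lattice geometry** (`lattice_builder`). One sized cell per
   element, merged into a single strut network and exported as watertight
   STL (voxel union + marching cubes) and wireframe CSVs.

Synthetic stand-ins for the study data live in `fixtures`: a three-tissue CT
phantom, a hemispherical-shell cage benchmark (with a bonded cage+bone
assembly variant) loaded with the 1962 N hip-joint resultant
(−408, 1919, 0) N, and box cantilevers.

## Worked example

```python
from latticeimplant import fixtures, ga_optimizer, surrogate

model = surrogate.SurrogateModel.with_reference_coefficients()
mesh, case = fixtures.make_cantilever(20, 10, 4)
cfg = ga_optimizer.GAConfig(seed=1, max_iters=80)
best, hist = ga_optimizer.optimize(mesh, None, model, cfg)
print(f"uniform-density compliance: {hist.compliance_per_iter[0]:.1f} N*mm")
print(f"optimized compliance:       {min(hist.compliance_per_iter):.1f} N*mm")
print(f"volume fraction: {best.mean_density():.4f}  density range: "
      f"[{best.rho.min():.3f}, {best.rho.max():.3f}]")
```

prints

```
uniform-density compliance: 2052.9 N*mm
optimized compliance:       1804.5 N*mm
volume fraction: 0.3990  density range: [0.200, 0.659]
```

i.e. at the same 40% material budget the graded design's compliance is ~12%
lower (stiffer) than the uniform lattice it was initialized from; it stays
inside the manufacturable/clinical density window [0.2, 0.7], and can be
handed to `lattice_builder.build` + `export_stl` for printing.

The same pipeline is scriptable end to end:

```bash
latticeimplant run-all --out runs/demo --seed 1
```

which writes the homogenization sweep CSV, surrogate JSON, GA history,
density VTK, lattice STL and a `summary.json` into the run directory.

## Layout

```
src/latticeimplant/   unit_cell, homogenization, surrogate, bone_material,
                      fe_solver, ga_optimizer, lattice_builder, fixtures,
                      vtkio, pipeline, cli
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       modelling assumptions, numerics, limitations
scripts/acceptance.py headline-number reproduction
```
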
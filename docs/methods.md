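# Methods

`stiffmatch` models the mechanics behind stiffness-matched porous superelastic
NiTi fixation hardware: a phase-transformation constitutive model for the
alloy, homogenization of a tri-cylinder pore unit cell on voxel finite
elements, inversion of the porosity–stiffness map against a cortical-bone
modulus target, local-stress safety checks, and a reduced
mandibular-reconstruction assembly for differential plate-material
comparisons. This note records the models, the numerical choices, and what
the synthetic geometry does and does not represent.

## Superelastic constitutive model

The alloy model (`stiffmatch.materials`) is a small-strain, rate-independent
phase-diagram model of the Boyd–Lagoudas/Auricchio family. The martensite
volume fraction ξ ∈ [0, 1] is the only internal scalar; the transformation
strain tensor has equivalent magnitude H·ξ and follows the deviatoric stress
direction (forward) or shrinks proportionally (reverse). Transformation is
driven by the von Mises stress q through linear stress–temperature lines

    forward:  q from C_M (T − Ms)  to  C_M (T − Mf)
    reverse:  q from C_A (T − As)  to  C_A (T − Af)

with linear hardening in ξ between start and finish. Elastic moduli follow a
Reuss (series) mixture of the austenite and martensite moduli; Poisson ratio
is constant. Above Af every mechanically closed loading path returns to zero
stress and ξ = 0, enclosing a dissipative flag-shaped loop — the defining
superelastic behaviour.

Default parameters (GPa, K, MPa/K): E_A = 37, E_M = 42, ν = 0.33, Mf = 243,
Ms = 263, As = 270, Af = 280, σ_y = 1011, operating temperature 310 K (body
temperature). The measured dense-alloy values fix the moduli, transformation
temperatures and yield strength. The stress–temperature slopes and the
transformation strain magnitude are not independently measured here; the
defaults C_M = C_A = 7 MPa/K and H = 0.04 are typical of Ni-rich NiTi in
compression, giving transformation stresses 329/469 (forward) and 280/210
MPa (reverse) at 310 K. `calibrate_from_curve` refits (C_M, C_A, H) to any
measured uniaxial loop by least squares, keeping the measured moduli and
temperatures fixed. Tension–compression asymmetry is ignored (a single H):
the use cases are compression-dominated. Shape-memory (sub-Af thermal
cycling) paths, plasticity beyond a yield flag, rate and fatigue effects are
out of scope.

The 1D integrator is a scalar return mapping solved with Brent's method
(tolerance 1e-8, strain capped at 6%). The 3D update is a vectorized radial
return on Gauss-point arrays: forward steps keep the trial deviator
direction, reverse steps shrink the stored transformation strain
proportionally; the scalar consistency equation is solved by 80 bisection
steps (~1e-8 relative). Under uniaxial stress the 3D update reproduces the
1D integrator to ~1e-9 relative (a dual-route test enforces 0.5%).

## Unit-cell geometry

The pore motif (`stiffmatch.lattice`) is three orthogonal cylinders of equal
diameter d meeting at the centre of a cubic cell of edge a. The cylinders
are void channels in solid metal (the convention flag also supports the
strut reading). The analytic void fraction follows from inclusion–exclusion
with the Steinmetz volumes (bicylinder 16r³/3, tricylinder 8(2−√2)r³):

    porosity(d, a) = [3π r² a − 16 r³ + 8 (2 − √2) r³] / a³,   r = d/2,  d ≤ a.

The maximum porosity of the family is 0.9420 at d = a. Porosity is strictly
monotone in d and in a, so cell dimensioning is one-dimensional root finding
(bisection to 1e-12). With 1 mm channels, a 45.7% void fraction requires
a ≈ 1.871 mm. Only the ratio d/a matters for homogenized (dimensionless or
modulus-ratio) quantities.

Plates (`PlateSolid`) tile the cell lattice inside a 0.2 mm fully dense
shell, with screw holes (1.4 mm) cut along a chosen axis. Printability
checks and graded lattices are out of scope.

## Voxel finite elements

`stiffmatch.fe` implements trilinear 8-node hexahedra on axis-aligned voxel
grids (anisotropic spacing allowed), 2×2×2 Gauss quadrature, sparse CSR
assembly, Dirichlet elimination, and Jacobi-preconditioned conjugate
gradients (relative tolerance 1e-8; sparse direct factorization below 15 000
free unknowns, which also makes the patch test exact to machine precision).
Element stresses are reported at centroids (mean of the Gauss points for
nonlinear materials) — maxima are element-centroid values, not nodal
extrapolations. Meshes with disconnected face-connected components are
rejected.

Superelastic solves ramp the loads proportionally (or along an explicit
load/unload schedule) with a Newton iteration per increment: residual
tolerance 1e-6 relative, consistent tangents that are analytic isotropic in
elastic branches and symmetrized central differences where transformation is
active, a backtracking line search (branch switches make the residual
non-smooth and undamped Newton can cycle), and increment halving up to four
cuts with step recovery.

Interfaces couple matched voxel faces with penalty springs (default
stiffness 100 × the stiffer neighbour's modulus × tributary area / voxel
edge). `tie` bonds all components; `contact` transmits compression only
along the plane normal and nothing tangentially — the friction-0 and
friction-1 endpoints of the healing and healed graft junction. Contact uses
an active-set iteration of linear solves; the superelastic solver couples
bonded interfaces only.

## Homogenization

`equivalent_curve` measures a cell the way a compression test is read:
uniform normal displacement on two opposite faces (frictionless platens),
lateral faces traction-free; equivalent stress = axial reaction / a²,
equivalent strain = face displacement / a, equivalent modulus = initial
slope. This uniaxial-stress family mirrors a physical compression test;
periodic homogenization would run slightly stiffer, and the choice is part
of the stated study conditions. For a dense cell the boundary conditions
are exact and the dense modulus is recovered to machine precision.

Two discretizations serve different purposes:

* **Composite voxels** (design loop): each voxel carries a stiffness scale
  equal to its solid volume fraction, computed from the signed distance of
  the voxel centre to the cylinder surfaces through a one-voxel linear ramp
  (a level-set density mapping, O(h) accurate). This makes the
  porosity → modulus map *continuous*: a binary voxel set is piecewise
  constant in porosity (nearby geometries voxelize identically), which
  defeats root finding outright.
* **Binary voxels** (local stresses, superelastic runs): solid if the voxel
  centre is metal. Local stress fields need an unambiguous material state
  per element, so peak-stress reports never use composite scaling.

The equivalent modulus converges within ~2% by 12–24 voxels per cell edge,
with non-monotone fluctuations of a few percent between resolutions as the
strut topology re-discretizes. The *local maximum* von Mises stress does not
converge at all: the curves where two cylinder surfaces intersect are
re-entrant edges of the solid and elastically singular, so the peak grows
under refinement for any mesh family (conforming meshes included — any
printed peak value is implicitly tied to its mesh). Peak-stress checks
therefore run at a stated convention density, the coarsest adequate mesh:
at least 4 voxels across the thinnest strut, rounded up to a multiple of 4,
floor 12 (`adequate_resolution`). Both the raw maximum and a
singularity-filtered maximum (a lone element exceeding the runner-up by more
than 3× is excluded) are reported; in the symmetric single cell the filter
rarely fires because the peak occurs in eight symmetric copies.

The local amplification factor (max local von Mises / equivalent stress) is
1 for dense cells and grows with porosity — roughly 3–4 at 44% and ~20 at
71% porosity at the convention density.

## Design loop and safety

`solve_porosity_for_modulus` inverts the porosity → modulus map for a target
equivalent modulus (default 12 GPa, the estimated average cortical-bone
modulus of the molar region; CT-based estimation is out of scope and the
target is a plain config input). A 9-point coarse sweep (24 voxels/edge,
composite) brackets the target; false-position refinement with full
resolution (48 voxels/edge) homogenizations converges to 0.1 GPa, capped at
3 fine solves by default (the map slope near the target is ≈ −45 GPa per
unit porosity, so a 0.1 GPa miss moves the porosity answer by under 0.3
points). At the defaults the loop places superelastic NiTi (37 GPa dense) at
≈ 44% porosity and Ti-6Al-4V (112 GPa dense) at ≈ 71% for the same 12 GPa
target. Published values for the same geometry are 45.7% and 78.3%; the Ti
gap reflects discretization families — thin-strut voxel models run softer
than coarse conforming tetrahedra, and the Gibson–Ashby open-cell scaling
(E/E_s = (1−φ)²) puts the Ti answer at 67%, bracketing ours.

`safety_check` drives the designed cell to the safety strain (default 2%,
the strain cortical bone can recover) and compares the filtered local
maximum against the yield strength; safety factor = σ_y / max local stress.
At the convention mesh density the porous NiTi design stays near 560 MPa —
below its 1011 MPa yield, with every local state on a recoverable
superelastic path — while the porous Ti design concentrates several GPa at
the pore edges and fails its 970–1030 MPa band decisively. That qualitative
asymmetry is robust to mesh density even though the Ti peak magnitude is
not.

## Reduced mandibular assembly

`stiffmatch.mandible` builds a deliberately simplified, prismatic
reconstruction: two host-bone segments (2 mm cortical shell over a
cancellous core; the host cortex uses the isotropic reduction E = 17 GPa,
ν = 0.315 of the published orthotropic "rest of mandible" row, the graft
the isotropic fibular values), a 40 × 14 × 38 mm double-barrel graft
bridging a 40 mm resection, one 78 × 4 × 1.5 mm inferior plate and two
18 × 2.8 × 1 mm superior plates on the buccal face. Screws are tie patches
(merged nodes within 2.2 mm of each screw axis): six inferior, two per
superior plate; elsewhere the plate–bone plane is split. The two host|graft
cuts are contact (healing) or bonded (healed) interfaces. Condyle end faces
are fixed; the bite resultant (60% of the healthy 526 N maximum) acts on the
top of the reconstructed molar segment at mid-span, so occlusal load must
cross the junctions — placing it on a host segment would route the shear
into the graft *through* the plates and invert the stiffness-matching
comparison on this reduced geometry. Pretension (default 100 N per plate)
is an axial contraction eigenstrain in the plate mid-spans, equilibrated
with the rest of the load; with equal nominal pretension the compliant
plate retains a larger fraction of it against the bone's finite stiffness,
which is the mechanical content of pretensioning superelastic hardware.

Desk-scale defaults use membrane-equivalent plates: one voxel through the
buccolingual thickness with the modulus scaled by (real thickness)/(modelled
thickness), preserving membrane stiffness (plate bending stiffness is
underrepresented; the comparisons are membrane-dominated). The
geometry-resolving preset (`AssemblyConfig.fine()`, ≥ 3 voxels across the
thinnest plate) is available for geometry work. The porous-NiTi arm uses the
homogenized 12 GPa plate response (linearized by default, a scaled
superelastic equivalent as an option); its reported plate stresses are
actual lattice stresses — homogenized stress × the pore cell's computed
elastic amplification — because a homogenized plate's raw stress is not
comparable with a dense plate's.

What the reduced assembly is for: *differential* orderings under identical
loads — graft-region stress higher with stiffness-matched plates in every
scenario, interface compression monotone in pretension, no tension across
contact interfaces, higher actual plate stress in the porous arm. What it is
not for: anatomical stress magnitudes, full-anatomy percentages or
plate-stress maxima, muscle-vector detail, screw thread mechanics, teeth or
periodontal structures. Passing its tests says the mechanics of stress
shielding and pretension are represented with the right signs and
monotonicities, not that any patient-level number is predicted.

## Problem sizes and determinism

Default problem sizes: design-loop homogenizations at 48 voxels per cell
edge (~65 000 elements for the NiTi cell), coarse sweeps at 24, local-stress
checks at the convention density (12–16), assembly comparisons at
(2, 2, 2) mm voxels (~6 000 elements) in tests and (1, 2, 2) mm in the CLI.
Everything is deterministic: fixed solver settings, no sampling; re-running
any command with the same configuration reproduces its outputs bit for bit.

## Known limitations

* Voxel (staircase) geometry is systematically softer than conforming
  meshes for thin struts; porosity answers at high porosity sit a few points
  below values computed on coarse conforming meshes.
* Peak local stresses at pore-edge singularities are mesh-density
  conventions, not converged quantities; only their yield/no-yield
  classification is robust.
* The superelastic model has a single transformation strain magnitude
  (no tension–compression asymmetry, no texture), linear transformation
  lines, and no plasticity or fatigue.
* Contact is restricted to planar matched-grid interfaces, compression-only
  and frictionless; intermediate friction factors are not modelled.
* The reduced assembly is prismatic and membrane-dominated; its absolute
  stresses are not anatomical.
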
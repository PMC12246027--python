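# Methods

This note documents the models, parameter choices, and numerical schemes in
`chondrosim`, and what the test suite does and does not establish.

## Constitutive model (material point)

Cartilage is a fibril-reinforced poroviscoelastic swelling continuum.

**Non-fibrillar matrix.** Compressible Neo-Hookean Cauchy stress

σ_nf = E/(3(1−2ν)) · ln J / J · **I** + E/(2(1+ν)) · (F Fᵀ − J^{2/3} **I**)/J,

which derives from the stored energy W = K/2 (ln J)² + G/2 (I₁ − 3 J^{2/3})
with K = E/(3(1−2ν)), G = E/(2(1+ν)); the verification tests differentiate
this energy numerically and compare at 10⁻⁶ relative tolerance.

**Collagen fibrils.** Primary fibrils follow the Benninghoff arcades
(surface-parallel in the superficial zone, depth-aligned in the deep zone,
linear angle interpolation across the middle zone with configurable zone
fractions); secondary fibrils use a fixed 13-direction near-isotropic set
(axes, face diagonals, body diagonals). Each fibril is tension-only. The
per-fibril stress obeys a viscoelastic law equivalent to a linear spring E₀
in parallel with a Maxwell branch whose spring is quadratic
(σ_s = E_ε ε_s²) and whose dashpot has viscosity η; in overstress form
s = σ_f − E₀ ε_f:

s + η ṡ / (2√(E_ε s)) = η ε̇_f.

The update is backward-Euler with a bracketed Brent solve per step; the
radicand is clamped at 10⁻¹² E_ε E₀ because the law is singular at s = 0.
Two consequences worth stating explicitly: (i) the algebraic rates-to-zero
equilibrium of this law is σ_f = E₀ ε_f (the Maxwell overstress η ε̇ vanishes
with the rate) — the quadratic E_ε term only shapes the transient stiffness;
(ii) over a 1-ms impact the branch relaxation time η/(2√(E_ε s)) is seconds,
so the branch contributes its spring tangent almost undamped.

**Flow and swelling.** Darcy flow with k = k₀ J^M; fixed charge density
(FCD) transforms as c_FCD = c_FCD,0 · n_fl,0/(n_fl,0 − 1 + J), which encodes
exact conservation of fixed charges (asserted to machine precision); Donnan
osmotic pressure Δπ = φ_int RT √(c_FCD² + 4(γ±_ext/γ±_int)² c_ext²) −
2 φ_ext RT c_ext; chemical expansion stress T_c = a₀ c_FCD
exp(−κ (γ±_ext/γ±_int) √(c⁻(c⁻ + c_FCD))). The mobile anion concentration
c⁻ is not an independent field: it comes from ideal Donnan equilibrium,
c⁻ = (−c_FCD + √(c_FCD² + 4(γ±_ext/γ±_int)² c_ext²))/2, exposed as a
swappable function. In the total stress the water chemical potential is
folded with the pore pressure into one effective pressure term; only total
boundary tractions are observable.

**Reference parameter preset ("mature bovine").** The full parameter table
behind the impact experiment is not public, so the preset uses
literature-style fibril-reinforced poroviscoelastic values: E_nf = 0.9 MPa,
ν_nf = 0.15, E₀ = 4.3 MPa, E_ε = 1.5 GPa, η = 1.06 GPa·s, C = 3.009,
k₀ = 3·10⁻¹⁶ m⁴ N⁻¹ s⁻¹, M = 5, bath 0.15 M, T = 310 K. Depth profiles
(FCD 120→250 mol m⁻³, fluid fraction 0.85→0.70, collagen density fraction
0.25→0.17) are smooth monotone curves in physiological ranges. Every
acceptance-relevant quantity is computed from configurable inputs, not from
this preset; the FE chain is therefore validated by physical properties
(below), not by printed numbers.

## Impact stage (axisymmetric finite elements)

Geometry: disc of radius 12.5 mm, thickness 1 mm; rigid flat indenter of
radius 2.5 mm with a 1-mm edge fillet. Structured bilinear quadrilateral u–p
mesh (default 60×24, radially graded toward the indenter edge; the
guarantee is the self-convergence test, not the element count).

*Swelling pre-state.* The Donnan + chemical-expansion pressure acts as an
isotropic eigenstress on the drained skeleton; Picard iteration updates the
deformation-dependent FCD to equilibrium. The driver is gauged to the
zero-FCD state (Δπ(c_FCD) − Δπ(0)) so charge-free tissue in bath equilibrium
is exactly stress-free even with non-ideal activity/osmotic coefficients.

*Impact.* Quasi-static Biot consolidation (no solid inertia, matching a
soils-consolidation analysis type) integrated backward-Euler with ≥ 50 steps
over the 1-ms half-sine. Contact uses the constant-area simplification:
nodes initially under the indenter are radially constrained and carry a
fillet-tapered vertical load that sums to the force waveform. Bottom fixed;
symmetry axis sealed; free surfaces drained; no flux under the indenter.
Storativity 4·10⁻¹⁰ Pa⁻¹ models fluid/grain compressibility.

*Linearization.* The element tangent combines the isotropic non-fibrillar
tangent with rank-one fibril stiffnesses along the arcade and secondary
directions. The fibril strain-stiffening is resolved by a damped secant
(Picard) fixed point: the transient solve is repeated with the fibril
linearization strain set to the geometric-mean-damped mean shear strain of
the loaded column until self-consistent (the strain→stiffness→strain map is
decreasing, so undamped iteration oscillates). The update is geometrically
linear about the swollen state; the reported γ_max is computed exactly as
(E_I − E_III)/2 from the Green–Lagrange tensor of the incremental
displacement field (an alternative convention without the /2 is a flag).
Strains are measured from the post-swelling configuration: damage
thresholds are impact-specific, so the swelling pre-strain is excluded
(config switch).

*Extraction.* Fields are evaluated at a fixed, mesh-independent probe grid
(matching the kinetics grid cell centers) at exactly t = 0.5 ms, the time
of peak force — not at the maximum of any nodal quantity. Mesh-independent
probes make zone averages comparable across mesh densities, so the
convergence check measures the solution rather than the sampling.

*What the FE tests show.* Short-time boundary drainage < 1 % of tissue
fluid; bottom reaction tracking the applied waveform within 5 % at peak;
positive pore pressure under the flat contact face; superficial-zone mean
γ_max changing < 5 % under 2× refinement; damage monotone in peak force
across 2000/4000/6000 N; strain concentrated under the indenter. They do
not certify strain magnitudes against the (unpublished) reference material
table — the biology stages are therefore driven by the reference synthetic
field in the quantitative comparisons (anti-circularity: mechanics is
tested by properties, biology by reported outcomes).

## Cell damage

f_dmg(ε) is 0 below ε_init = 0.40, 1 above ε_max = 1.50, and
(ε_max/ε)(ε − ε_init)/(ε_max − ε_init) between — continuous, nondecreasing
in ε, nonincreasing in ε_max (which reproduces the 65 %/56 %/52 % ordering
of the saturation-threshold sensitivity). Initial populations:
C_dmg = f_dmg·C_init, C_h = (1 − f_dmg)·C_init, C_dead = 0, with
homogeneous C_init = 0.5·10¹⁴ cells m⁻³. Strains are transferred to the
kinetics grid by nearest-centroid lookup.

Reporting zones (configurable): "superficial impacted" = top 200 µm,
r ≤ 2 mm (matching the 4-mm-wide dissected core of the source
experiments); "impacted" (proteoglycan readout) = full-depth r ≤ 2 mm;
"intact" = full-depth annulus 8–10 mm. Zone averages are 2πr
volume-weighted. Zone scalars are reported as averages; a point-value mode
exists because the experimental readout could be either.

## Biokinetics

Finite-volume discretization on the axisymmetric cell-centered grid
(default 40×20 over 12.5 mm × 1 mm). Operator splitting per step:
implicit (backward-Euler) diffusion for NAC and enzyme first — so a freshly
applied bath acts within the step — then reactions via exact exponential
sub-updates:

- damaged→dead at k_death and damaged→healthy at k_rec·C_NAC are competing
  first-order channels; the exact split conserves C_h + C_dmg + C_dead to
  rounding error (asserted ≤ 10⁻¹⁰ relative every run) and preserves
  positivity;
- stimulus relaxes exactly toward k_aga·C_dmg (midpoint damaged level);
- enzyme: production S, first-order clearance k_enz_clear;
- proteoglycan: semi-implicit (positivity-preserving) update of
  dC_PG/dt = −k_cat·C_enz·C_PG/(K_M + C_PG) − k_basal·C_PG +
  β_syn·viable_fraction.

No spontaneous basal death or recovery of cells (unimpacted controls change
< 5 % over 3 days in the source experiments). NAC has no sources or sinks
in the tissue; its bath is a Dirichlet condition on the top and outer
surfaces, switched by the treatment schedule (step on at `delay`, off after
`duration`, then 0 mM for free out-diffusion at the media change). An
untreated schedule means no bath was ever present, hence zero-flux NAC
boundaries. Enzymes default to zero-flux on all boundaries (an outflux
alternative is configurable). Enzyme diffusivity is matrix-dependent:
D_enz = D_enz0·exp(−a·C_PG/C_PG,init), monotone decreasing in local
proteoglycan.

**Transport and kinetic defaults.** D_NAC = 1.2·10⁻¹⁰ m² s⁻¹ — the
free-water-scale diffusivity of a 163-Da solute reduced for the cartilage
matrix; a value of 1.2·10⁻⁴ m² s⁻¹ sometimes quoted for NAC exceeds
free-water diffusion by five orders of magnitude and is physically
impossible, so it is available only behind an explicit switch. The
superficial-zone outcomes are insensitive to the choice (both equilibrate
the top 200 µm in ≪ 1 h; the physical value does so in ~6 min, asserted by
test). Enzyme-side constants are not published: D_enz0 = 5·10⁻¹² m² s⁻¹
(60-kDa aggrecanase scale), K_M = 100 mol m⁻³ (comparable to initial
proteoglycan in FCD-equivalent units), k_cat = 5·10⁻⁴ s⁻¹,
k_enz_clear = 10⁻⁵ s⁻¹ (~1-day clearance), basal proteoglycan turnover
k_basal = 2·10⁻⁸ s⁻¹ with biosynthesis β_syn = k_basal·C_PG,init so intact
tissue is at steady state by construction; biosynthesis scales with the
viable (healthy + damaged) fraction — damaged cells keep synthesizing until
dead. Intact proteoglycan is immobile; degraded fragments leave the intact
pool instantly (only intact content is compared to measurements). The
single free scalar k_aga is calibrated (below); all other arms are
predictions.

**Calibration.** k_aga is found by a bracketed false-position (Illinois)
iteration — a damped bisection variant — on the untreated day-14
impacted-vs-intact deficit, target 14 %, tolerance 0.2 percentage points.
The deficit is monotone and near-linear in k_aga (the stimulus equation is
linear and degradation is near-zeroth-order in proteoglycan), so the solve
converges in a handful of 14-day runs.

**Exposure-integral surrogate.** Because the stimulus integrates C_dmg
linearly, total enzyme production — hence, to first order, the deficit —
scales with ∫C_dmg dt. Arm ratios follow in closed form:
immediate/untreated = k_death/(k_death + k_rec·C_NAC) ≈ 0.39; 4-h delay
≈ (1−e^{−k_d t_d}) + e^{−k_d t_d}·0.39 ≈ 0.78. The full PDE tracks these
within 1.5 percentage points; the residual gap for the immediate arm
(~1 point above the surrogate) is the depth-diffusion lag of NAC — cells
deep in the 1-mm tissue see the bath only after ~1–2 h, an effect the
well-mixed surrogate cannot represent.

**Well-mixed viability reduction.** Closed form used as the oracle and the
fast engine for superficial-zone viability: death-only decay before the
bath onset, competing rates k_death and k_rec·C_NAC after it, viability
= 1 − dead fraction. It reproduces the printed viabilities within ~1.5
points; the residual offset is the spatial-averaging gap of the PDE.

**Time stepping.** dt = 60 s for day-scale runs; dt = 1 s during the first
hour after bath onset (steep NAC boundary layers); stiffness sits in
diffusion (implicit), reactions have ≥ hour timescales (explicit-exact).
The enzyme diffusion operator is refactorized every 60 steps as the
proteoglycan field evolves. Phase boundaries (bath on/off, record times)
are hit exactly by step-size clipping.

## Problem sizes

Quantitative comparisons run on the 40×20 kinetics grid (800 cells;
14-day arm ≈ 5 s); the FE property checks use 30×12 vs 60×24 meshes with 50
implicit steps and a 10-pass secant loop (≈ 15 s total). These sizes sit
beyond the knee of the convergence curves (the 2×-refinement change in the
superficial strain average is ~4 %).

## Known limitations

- The impact stage is a linearized (secant-stiffened) Biot model, not a
  finite-strain poroviscoelastic solve; strain magnitudes depend on the
  unpublished material table and are validated by properties only.
- No contact friction, surface lesions, osteochondral-junction damage, or
  fluid leakage through cracks; no solid inertia (quasi-static).
- No inflammation, cytokines, necrosis/apoptosis split, proliferation, or
  explicit ROS dynamics (oxidative stress is implicit in the damaged-cell
  pool); NAC is not consumed, which if anything overstates its efficiency.
- Degradation-induced softening of the matrix is not fed back into the
  mechanics.
- The synthetic reference strain field encodes the reference superficial
  damage outcome with a flat-top radial profile; it does not emulate
  confocal-imaging noise or assay variability, so passing tests demonstrate
  the model chain, not agreement with raw experimental images.
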
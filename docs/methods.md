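# Methods

`gkdosim` is a fully synthetic test bench for verifying convolution-style
dose calculation in stereotactic radiosurgery when the target sits next to
bone and air. Every stage a physical verification study needs — phantom,
CT, density calibration, dose calculation, film dosimetry, registration,
gamma analysis, uncertainty budget — exists as code, so the whole chain
can be exercised, seeded and re-run without any measured data. This note
records the models, the defaults and the limits of what passing tests
demonstrate.

## The phantom and its synthetic CT

The phantom is a 160 mm solid-water sphere centred on the unit center
point (UCP, (100, 100, 100) mm in the stereotactic frame) whose central
slabs are water-equivalent RW3 carrying:

* a mirrored-C bone inset, modelled as three axis-aligned boxes — two
  lateral bars 1.5 cm thick in x and a posterior bar 1 cm thick in y, all
  6 cm long in z — abutting a 2×2×6 cm³ RW3 core;
* a 1.5×2×6 cm³ air cavity on the open side of the C;
* three metal fiducial pins (z-cylinders, radius 1 mm) near the slab
  periphery at radius 70 mm.

The pins sit at deliberately scalene angles (80°, 200°, 330°). A
symmetric pin triangle would make the pin ↔ hole correspondence
ill-posed: swapping two symmetric fiducials is itself a rigid motion, so
no fiducial-based registration could detect the mix-up. Voxelisation
guarantees each pin marks at least the voxel column nearest its axis, so
fiducials stay resolvable at any CT spacing.

Materials carry the measured relative electron densities of the physical
materials (RW3 0.993, solid-water shell 1.013, bone substitute 1.605; air
0.0011) and their measured mass densities. The synthetic CT pushes each
material's η through the *inverse* of the scanner calibration curve and
adds seeded Gaussian HU noise; metal pins sit on a fixed 3000 HU plateau,
mimicking clinical metal saturation outside any calibration range. The
default calibration curve is a two-segment 120 kVp-like polyline through
(−1000, 0.001), (0, 1.0), (1600, 1.9); worked-example tests feed η
directly and do not depend on it.

## Density conversion

The convolution pathway maps HU → η through the calibration curve
(piecewise linear, clamped outside the breakpoint range so noise can
never produce negative density) and derives mass density with the
continuous piecewise rule

ρ = η for η ≤ 1,  ρ = (η − 0.15)/0.85 for η > 1.

Both branches meet at η = 1. This rule reproduces the three phantom
materials to the printed precision (0.993 → 0.993, 1.013 → 1.015,
1.605 → 1.7118) and is pinned by unit tests. The MC pathway maps HU → ρ
directly and bins ρ into a compact five-class Schneider-style
density → elemental-composition table (air, lung, adipose, soft tissue,
bone); the full 24-bin table can be supplied by configuration but is not
needed by any packaged computation.

## Machine model and absolute dose chain

The source geometry is 8 sectors × 24 sources = 192 ⁶⁰Co sources on five
latitude rings of a cone at 400 mm source–focus distance, each sector
owning a disjoint 45° azimuthal wedge, every source aimed at the focus.
Ring angles and the source–focus distance are configurable; nothing
downstream depends on the exact placement — counts, normalisation and
ratios are what the tests pin.

Absolute dose traces back to an ionization-chamber measurement at the UCP
of the water sphere with the 16 mm field:
D = M·k_TP·k_pol·k_ion·N_D,w·K_Q,Qo·K_Qmsr, with the machine-specific
reference-field correction defaulting to 1.0037, decay-corrected with
T½(⁶⁰Co) = 5.2711 y. Prescription normalisation sets the maximum dose to
prescription / (isodose fraction) — 4 Gy at the 50 % isodose gives an
8 Gy maximum — and the beam-on time follows from the reference dose rate
(default 3.215 Gy/min).

## Deterministic kernel engine

The engine is a structural analog of a collapsed-cone convolution
algorithm, not a reimplementation of any vendor's kernels (those are
proprietary). Per source and point:

primary = OF_c · (SFD/r)² · exp(−μ·d_rad) · ½ erfc((o − R_c)/(√2 σ_eff))

where d_rad is the radiological path length (line integral of ρ, g/cm²),
μ = 0.063 cm²/g (⁶⁰Co narrow-beam water value, configurable), o the
off-axis distance projected to the focus plane, R_c the nominal field
radius (collimator/2) and σ_eff the per-collimator penumbra width
stretched by the ratio of radiological to geometric depth (clipped to
[0.5, 2.5]). Scatter is the primary convolved with an isotropic
exponential kernel whose range is the 12 mm water value divided by the
mean phantom density, with a per-collimator amplitude. Relative output
factors default to 1 / 0.9 / 0.814 for 16 / 8 / 4 mm.

Numerics: the scalar `beam_dose` uses an exact Siddon voxel traversal for
d_rad; the vectorised plan engine uses 32-point midpoint sampling per ray
(float32 coordinates), verified against the Siddon form in tests. Points
more than ten maximally stretched penumbra widths outside the field edge
are set to exactly zero (erf tail < 1e-20). The dose grid defaults to the
shot bounding box plus a 30 mm margin with the UCP anchored on the
voxel-center lattice.

Absolute scaling divides the relative dose by the engine's own relative
dose at the UCP of the homogeneous water sphere (16 mm field) and
multiplies by Ḋ_ref × BOT. The reference run re-uses the plan grid's
shape, spacing and density discretisation, so the calibration *closes
exactly* in the reference configuration — a structural identity the
acceptance tests check to 0.1 %. Because kernels and output factors are
package defaults rather than vendor data, absolute beam-on times are not
comparable to any commercial system; density handling, normalisation and
geometry are the modelled content.

## MC-lite stochastic engine

MC-lite samples a (shot, sector) category per photon history from
P_i = t_i·N_i / Σ t_j·N_j (sector active time × phase-space particle
count), picks a source uniformly within the sector, aims at a uniform
point in the collimator disc at the focus plane, and marches the ray in
1 mm steps from its entry into the density grid, depositing
ρ·exp(−μ·d_rad)·Δl per step into the scoring voxel. One stochastic
scatter kick (exponential depth, Gaussian 20° deflection) stands in for
higher-order scatter. Per-voxel statistical uncertainty is the batch
method: the standard error of the batch means (default 10 batches).
Uncertainty scales as the expected inverse square root of history count
(slope −0.5 ± 0.1 in tests). Absolute scaling follows the same reference
chain, with the reference normalisation computed by MC-lite itself in
the water sphere under an independent seed.

There is no electron transport. Charged-particle disequilibrium — the
physical reason a convolution algorithm overestimates dose inside an air
cavity — is therefore reproduced only qualitatively (reduced deposition
in low-density voxels), and the packaged dose-to-medium factors are not
re-derivable by this engine. That is a declared fidelity boundary, not an
approximation to be tightened.

## Film simulation and dose-to-medium conversion

A film is a planar raster (default 0.169 mm/px, the flatbed-scanner
pitch) embedded in the stereotactic frame, by default the central axial
plane. Simulation samples the 3D dose trilinearly at (optionally rigidly
perturbed) pixel positions, multiplies by (1 + ε), ε ~ N(0, noise
fraction), and punches zero-dose holes where the pins lance the film.
Because a film calibrated in a ⁶⁰Co water beam reads dose-to-water even
inside bone or air, the simulator divides the sampled dose-to-medium by
the per-medium conversion factor where a label grid is supplied, and the
film records its per-pixel medium masks at exposure time (the physical
film piece is cut to fit the slab, so the media it lay in are known by
construction).

The conversion factors K_med = (D_med/D_film at treatment geometry) ×
(D_film/D_w at calibration) are packaged constants per medium and field
size (bone 0.941/0.946/0.946, air 0.745/0.748/0.749 for 16/8/4 mm),
taken from full Monte Carlo transport published for this phantom family;
users may supply their own table as CSV. Plan-level factors are the
unweighted arithmetic mean over the distinct field sizes the plan uses
(0.944 bone, 0.747 air for the three-field mix); a time-weighted variant
exists behind a keyword. Conversion multiplies masked pixels by their
factor, flips the reporting-medium flag, and refuses a second
application.

## Registration

Pins appear as bright CT blobs (intensity-weighted centroids above a
2000 HU threshold; exactly three components required) and as zero-dose
film holes (geometric centroids of exactly three components). The rigid
fit is the closed-form Kabsch/Procrustes solution with a reflection
guard: mirrored correspondences raise rather than silently flipping.
Because three points admit six pairings and no ordering convention
survives arbitrary rotations, the pairing is resolved by the lowest-RMS
fit over all permutations — unique for a scalene pin triangle. With
coplanar fiducials the out-of-plane sign of the rotation is intrinsically
ambiguous, but both solutions agree identically on the film plane itself,
which is the only surface ever resampled. Planning dose is brought onto
the film raster by trilinear interpolation through the fitted transform.

## Gamma analysis

γ at a reference point is the minimum over evaluated points of
√(|Δr|²/DTA² + ΔD²/(f·D_ref)²), local normalisation (f = 3 % of the
reference point's own dose), DTA 1 mm, 1 Gy dose cut-off, evaluated over
the evaluated distribution resampled to a 0.1 mm lattice. The fine step
matters: penumbra gradients reach ~30 %/mm, so a coarser lattice
quantises the dose-difference term by more than the criterion itself and
manufactures false failures. The search is windowed to 3×DTA with a
sorted-offset early exit; an exhaustive mode (`search_radius_mm=inf`)
serves as the brute-force oracle, and tests pin the two equal to 1e-9.
The window is a superset of the radius ball, so the capped search can
only ever lower γ towards the exhaustive value. The film (or MC) map is
the reference and the planning dose the evaluated distribution; which
map is resampled is configurable since the formalism is asymmetric either
way, and a regression fixture pins one asymmetric pair.

## End-to-end verification and uncertainty reporting

`run_verification` chains all stages under one seeded config and reports
passing rates with and without the air cavity, the registration residual,
the beam-on time, the K_med factors used and the quadrature uncertainty
budgets (calibration 0.9 %, film 2.0 % at one decimal, half-up display
rounding; raw values retained). Reports are byte-identical under a fixed
seed. Default problem sizes — 1 mm synthetic CT, 2 mm dose grid, 0.5 mm
film pitch over 150 mm — keep a full run in the low minutes on one core;
they are the package's chosen verification conditions, with the CT-native
0.53 mm and film-native 0.169 mm pitches available by configuration.

What the passing tests do and do not show: the noiseless self-consistent
chain demonstrates that registration, resampling, medium conversion and
gamma bookkeeping introduce no artefacts (100 % excluding air), and that
*omitting* the dose-to-medium conversion is detected as a failure
concentrated in the air cavity — the structural contrast a physical
verification study exhibits. They do not validate the engine's absolute
dosimetry against a clinical system: the kernels are package defaults,
there is no electron transport, and film-response chemistry is out of
scope (films are simulated directly in dose).

## Known limitations

* Kernel parameters (μ, penumbra widths, scatter range/amplitude, output
  factors) are plausible water-medium defaults, not fitted vendor data.
* MC-lite is photon-only ray marching with a single scatter kick; no
  electron transport, hence no ab-initio K_med and only qualitative
  air-cavity disequilibrium.
* The mirrored-C bone region is three axis-aligned boxes; curved or
  oblique interfaces are not modelled.
* Registration assumes exactly three well-separated, scalene fiducials;
  there is no intensity-based fallback.
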
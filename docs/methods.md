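# Methods

## Coordinate conventions

All coordinates are in ångströms in a right-handed frame.  The pore
(three-fold symmetry) axis is +z with the extracellular side at larger z.
Residue numbering is author/PDB numbering in the chicken ASIC1 scheme; the
rat ASIC3 equivalence (e.g. Glu435 ↔ Gly429) is a mapping the caller
supplies, never arithmetic performed by the package.  When a periodic box is
present all distances use the minimum-image convention; otherwise plain
Euclidean distances.  Trimer generation uses exact C3 symmetry (120°/240°
rotations about a given axis), not crystallographic symmetry operators;
subunits are relabelled A/B/C in rotation order with the source label kept
as metadata.  Alternate-location conformers resolve to the highest
occupancy, ties to the first encountered.

## Pore-axis alignment

The pore axis is taken as the smallest-moment principal (inertia) axis of
the Cα atoms, which is the bundle axis for a prolate helix-bundle geometry
like a transmembrane trimer; the structure is rotated so this axis is +z
and recentred at the origin.  The eigenvector sign is chosen to make the
rotation minimal, so alignment is idempotent and an already-aligned
structure is returned unchanged.  A near-degenerate inertia spectrum (no
preferred elongation) or collinear input raises rather than guessing.  Flat,
oblate assemblies would violate the smallest-moment assumption; the
synthetic scaffold is built prolate (30 Å rods at ≤ 10 Å radius) so the
assumption holds throughout the package's own systems.

## Pore aperture

Aperture at a pore-lining position is the area of the triangle through the
three symmetry-related Cα atoms, `½|(p₂−p₁)×(p₃−p₁)|`.  Distributions are
normalised histograms over an analysis window defaulting to the last 30% of
frames (mirroring the practice of analysing the final stretch of a
production run); the Freedman–Diaconis rule sets the default binning, with
a fixed bin count and a Gaussian-KDE variant available for reproducibility
and smoothness studies.  "Peak area" is the modal bin centre — the
distributions are plotted and quoted by their peaks in the source
experiments without a stated estimator, and the mode is the estimator that
matches a quoted "peak value".  Percent change between conditions is
`100·(peak_alt − peak_ref)/peak_ref`.

## Ca²⁺ coordination

Ligands are atoms of recognised chemistries within per-chemistry cutoffs of
the ion: carboxylate O (Asp OD1/OD2, Glu OE1/OE2), backbone carbonyl O,
water O (residues HOH/WAT/TIP3/SPC, configurable) and thiolate S (Cys SG).
Defaults are Ca–O 3.0 Å and Ca–S 3.2 Å — first-shell Ca²⁺–O distances
cluster near 2.4 Å, so 3.0 Å separates shell from second sphere cleanly;
no cutoff is prescribed by the source experiments.  A carboxylate donating
both oxygens (bidentate) contributes two ligands to the coordination
number, the reading consistent with bidentate coordination being invoked
for CN > 6.

Geometry classification compares ion-centred unit vectors with ideal
templates — octahedron for CN 6, pentagonal bipyramid for CN 7 — over all
vertex assignments and rigid rotations.  The implementation alternates
optimal assignment (Hungarian algorithm on the squared-angle cost matrix)
with Kabsch rotation refits, started from a deterministic family of
rotations (template vertex 0 mapped onto each observed direction, five
rolls each); the tests hold it equal to an exhaustive search over all
vertex permutations.  The fit metric is the angular RMSD (degrees) between
observed and matched template directions; labels are accepted up to 15°,
above which (or for unsupported CN) the shell is `other`, as is an exact
tie between templates.  Rigid rotations change neither CN, label nor RMSD.

The multisite ("dummy-atom") cation model places `n ≤ 6` satellite charges
at octahedral directions around a central atom, with the central charge set
so the total is exactly +2 e.  Refitting Lennard-Jones or charge parameters
against hydration free energies is out of scope; the model here serves
geometry and charge-layout consumers, and its PDB writer stores per-atom
charges in the B-factor column (a documented convention).

## Hydration and transport

The axial water density is a 1-D Gaussian kernel profile: each water oxygen
contributes a Gaussian of width σ = vdW(O) × radius_scale (radius scale 2
by default, reproducing the heavier smoothing used for trajectory density
maps).  Each atom's kernel is normalised to unit mass on the evaluation
grid, so the profile integral equals the mean water count regardless of the
smoothing radius — an invariant the tests check by quadrature.  This is a
kernel-density emulation of a voxel-map tool, not bit-compatible with any
particular implementation.

A water wire is a path of water oxygens with successive O–O distances
within 3.5 Å (the hydrogen-bond heavy-atom convention; no cutoff is stated
by the source) connecting the region below the gate to the region above it.
Connectivity is evaluated on a KD-tree contact graph with sparse connected
components; tests pin it to a brute-force breadth-first search.  The gate
region defaults to the z-interval of the Asp433 ring ± 2 Å.  The synthetic
generator plants wire chains at 3.4 Å spacing — just under the cutoff — so
detection is unambiguous at the default threshold.

Gate crossings of an ion are counted with a ±1 Å hysteresis band around the
gate plane: a crossing requires passage from beyond one side of the band to
beyond the other, so thermal jitter around the plane is never
double-counted.

Binding-energy frames follow the end-point scheme: per frame the ion is the
ligand and the receptor is the protein plus the five waters closest to the
ion (k configurable); all other solvent and counterions are stripped.
Distance ties at rank k break deterministically by atom serial.

## Simplified interaction energies

The interaction comparator computes gas-phase molecular mechanics over
receptor × ligand pairs: Coulomb `Σ 332.0636·qᵢqⱼ/(ε(r)·rᵢⱼ)` with a
constant or distance-dependent (ε(r) = k·r) dielectric, plus Lennard-Jones
in the r_min/well-depth form.  Generalized-Born and surface-area terms are
deliberately not implemented: the published relative-affinity numbers
(~20%/~40%) depend on microsecond trajectories and a specific GB
parameterisation, so they are not reproduction targets here.  Relative
affinity is quoted as `100·(⟨E_B⟩ − ⟨E_A⟩)/|⟨E_A⟩|` with more-negative =
stronger binding; the sign flips under system swap, while the magnitude is
referenced to system A (the comparison form in which "x% higher affinity"
statements are made).

## Electrophysiology statistics

The activation model is the Hill curve on the pH scale,
`I(pH) = I_max/(1 + 10^{n_H(pH − pH₅₀)})`, which gives half-maximal current
at pH₅₀ and is the proton-concentration Hill function re-expressed in pH.
The source describes fitting with "a logarithmic equation" without writing
it; this form is the one consistent with the quoted pH₅₀/n_H pairs.
Fitting is deterministic: the amplitude is profiled out analytically on a
coarse grid (pH₅₀ ∈ 6.0…8.0 step 0.2 × n_H ∈ {0.5, 1, 2, 4, 8}), and the
best grid point seeds a single bounded Levenberg–Marquardt refinement.
Standard errors come from the Jacobian at the optimum.  Flat data and
asymptote-only data (no point between 2% and 98% of the response range)
raise as unidentifiable.

Curve comparison uses the extra-sum-of-squares F test,
`F = ((RSS_sh − RSS_sep)/(df_sh − df_sep))/(RSS_sep/df_sep)`, with p from
the F distribution; when both models fit to numerical precision
(noise-free data) the test reports F = 0, p = 1 rather than amplifying
rounding error.  Group comparisons from summary statistics recover the sd
as sem·√n and use the pooled (Student) variance by default — matching the
source's stated test — with Welch–Satterthwaite available.  All p-values
are two-sided; no multiple-testing correction is applied (none was in the
source).  Published p-values are not reproduction targets: they derive from
raw per-cell data that is not deposited.

## Synthetic study systems

The generators are deterministic under a fixed seed (bitwise-reproducible).

* **Coordination fixtures** place the ion at the origin and roster ligands
  at ideal polyhedron vertices at the bond length (2.4 Å default), with
  optional Gaussian angular jitter.  A bidentate carboxylate occupies two
  adjacent vertices (90° octahedral, 72° equatorial) with its carboxylate
  carbon 2.2 Å behind the O–O midpoint.  The two rosters shipped as
  constants are the observed site compositions: the mutant site (three gate
  aspartates, one bidentate; one glutamate; two waters; CN 7) and the
  wild-type site (one aspartate oxygen per subunit; three waters; CN 6).
* **The pore scaffold** is a C3 trimer of Cα rods along +z (1.5 Å rise per
  residue, position 433 at z = 0) with marker rings at 429/433/436 at
  prescribed radii; the ring circumradius r gives triangle area
  (3√3/4)·r².  Trajectories realise per-frame ring areas as Gaussian draws
  around the target mean, place waters in piecewise-uniform axial slabs
  within a 10 Å pore radius, rearrange waters into a gate-spanning chain in
  designated frames, and optionally add a bound divalent ion above the gate
  and monovalent ions higher in the vestibule.
* **Dose-response data** are Hill curves with additive Gaussian noise (a
  fraction of I_max) per cell and measurement — the simplest model that
  supports parameter-recovery tests.  Area distributions are unimodal
  Gaussian by default; no target distribution shapes beyond peaks are
  available to emulate.

What the synthetic systems deliberately do not carry: physically realistic
water/lipid packing, force-field energetics of the fixtures, correlated
(non-Gaussian, autocorrelated) fluctuations of microsecond MD, or
cell-to-cell amplitude heterogeneity beyond additive noise.  Passing tests
therefore demonstrate the correctness of the measurement machinery on
systems with known ground truth, not the MD-scale observations themselves;
the headline trajectory-dependent numbers (the ~167%/~68% peak-area
increases, the ~20%/~40% relative affinities) are consequently exercised as
arithmetic on synthetic inputs, not reproduced from physics.

## Problem sizes and numerical choices

Synthetic trajectories use 600 frames in the analysis drivers and 1000
frames for the rare-event wire-probability study (one planted wire frame →
0.10%); shells use ≤ 7 ligands, where exhaustive assignment (≤ 5040
permutations) remains cheap enough to serve as a test oracle.  Recovery
studies use 200 seeded replicates (Hill fitting) and 500 (F-test type-I
calibration, nominal α = 0.05, acceptance band 0.02–0.08 ≈ ±3 binomial σ).
Histogram normalisation is checked to 1e-9; geometric invariances to 1e-9;
fixture geometry to 1e-6°.  Degenerate inputs fail loudly: zero symmetry
axes, collinear rings, flat dose-response data, empty selections and
atom-count mismatches all raise with context.

## Known limitations

* No mmCIF parsing; PDB and DCD only.
* The principal-axis convention assumes prolate assemblies.
* Geometry templates cover CN 6 and 7 only; other CNs classify as `other`.
* The energy comparator omits solvation entirely; only relative,
  like-for-like comparisons are meaningful, and no absolute binding free
  energy is ever produced.
* Accession-based checks on deposited crystal structures (e.g. the 22–30 Å
  glutamate-ring diameter or the ~55 Å pocket-to-gate separation in a real
  trimer) require coordinates that are not bundled; the corresponding
  operations are validated on synthetic structures with known geometry.
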
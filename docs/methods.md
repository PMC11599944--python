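# Methods

## Scope and data flow

The package covers the analysis layer of an NMR crystallography study:
it consumes tensors that a periodic DFT (GIPAW) code has already produced
and experimental shift tables that a spectroscopist has already assigned,
and computes everything in between — referenced shifts, quadrupolar
parameters, geometry-derived pair lists, predicted 2D peak positions and
discrepancy statistics.  The DFT stage itself (geometry optimisation,
shielding/EFG calculation) is out of scope; its role in tests is played by
the synthetic generator described below.

## File formats

**.magres (v1.0 block layout).**  `[atoms]` holds `units`, one `lattice`
line (9 components, row vectors, Å) and `atom <species> <label> <index>
x y z` lines; `[magres]` holds `ms <label> <index> <9 components>` (ppm)
and `efg …` (atomic units) lines.  Only these units are accepted; any
other declared unit is rejected loudly rather than silently converted.
Unknown blocks are ignored.  The writer orders atoms by (species, index)
and prints full double precision, so serialisation is byte-deterministic
and `parse(write(d))` is an exact identity.  Raw tensors are kept as read;
symmetrisation (T + Tᵀ)/2 happens only at the point of eigen-analysis,
because GIPAW shielding tensors may carry antisymmetric parts that do not
affect the isotropic value.

**Structures.**  A CIF subset (cell lengths/angles + `atom_site`
fractional loop, parsed via gemmi) and an XYZ-with-cell fixture format
whose comment line carries the 9 cell components (Cartesian coordinates).
Fractional coordinates are wrapped to [0, 1) on construction; Cartesian
positions are `frac @ cell` with the row-vector cell convention, stated
once and used everywhere.  Structures are treated as P1; symmetry-operator
expansion is not performed.

## Periodic geometry

Minimum-image distances wrap the fractional difference to the nearest
image and search the 27 surrounding translations.  Exhaustive image
enumeration (`distances_within`) sizes its search box as
⌈cutoff / h_min⌉ + 1 translations per axis, where h_min is the smallest
perpendicular cell height — complete for arbitrarily skewed cells.  Both
are checked against an independent brute-force 5×5×5 enumeration oracle
on random triclinic cells in the test suite.

Hydrogen bonds are found geometrically: each H is attached to its nearest
donor heavy atom within a covalent cutoff (C–H 1.1 Å; N–H and O–H 1.2 Å,
configurable), and a D–H⋯A contact is recorded when the minimal-image
H⋯A distance is ≤ 2.5 Å and the D–H–A angle (vertex at H, evaluated at the
image realising the minimal H⋯A distance) is ≥ 120°.  The distance/angle
defaults are a package decision — hydrogen-bond surveys in the field use a
range of criteria — chosen permissive enough to capture the NH⋯O contacts
of the shipped API dataset while excluding bent, long contacts.
H–H proximity lists include self-pairs (a proton within the cutoff of its
own periodic image, as methyl groups at cell boundaries are), and report
every image distance within the cutoff, not just the minimum, since
distinct images contribute distinct dipolar contacts.

## Referencing

δ_iso = σ_ref − σ_iso.  Three σ_ref modes:

* fixed per nucleus (¹H 31 ppm, ¹⁵N −160 ppm);
* piecewise for ¹³C: 172 ppm for shifts at/above 45 ppm, 175 ppm below.
  Classification uses the *first-pass* shift computed with the
  above-threshold reference; if that value falls below 45 ppm the shift is
  recomputed with the below-threshold reference.  This is deterministic
  and unambiguous whenever sites sit clearly on one side of the threshold
  (the shipped datasets have no site within 3 ppm of it); a first-pass
  shift within |172 − 175| = 3 ppm of the threshold logs a
  classification-ambiguity warning.
* fitted: σ_ref = mean(δ_exp + σ_calc), the closed-form minimiser of the
  RMSD between experiment and σ_ref − σ_calc.  After this fit the mean
  residual is zero by construction, which the comparison module uses as a
  cross-check.  An OLS `regression_slope` is provided for diagnosing the
  slope ≠ −1 of shift/shielding correlations but is deliberately not
  applied to headline outputs, which use fixed or mean-fitted σ_ref.

Equivalent-site averaging (methyl ¹H triplets rotating fast on the NMR
timescale) is an arithmetic mean over a caller-supplied grouping.

## Quadrupolar arithmetic

EFG eigenvalues are ordered |V_zz| ≥ |V_yy| ≥ |V_xx|; a magnitude tie
between V_zz and V_yy (within 1e−10) is broken toward the algebraically
larger eigenvalue so output is deterministic.  C_Q = eQV_zz/h with the
conversion constant 234.9647 MHz·barn⁻¹·a.u.⁻¹ and Q(¹⁴N) = 0.02044 barn
(Pyykkö 2008 compilation) fixed as named constants.  η is defined 0 when
C_Q = 0.  P_Q = |C_Q|√(1 + η²/3) is kept non-negative; the sign that a
table of calculated values may attach belongs to V_zz and is exposed
through C_Q.

The second-order isotropic shift is (3/40)(P_Q/ν₀)²·10⁶ ppm — the spin-1
single-quantum expression with no further transition-dependent prefactor —
and its inversion P_Q = ν₀√(40 δ_Q/3·10⁶) is exact, which the tests verify
to 1e−9 MHz over P_Q ∈ [0, 10] MHz.  A negative apparent δ_Q (observed
¹⁴N below the chemical shift) has no real P_Q solution and is returned
with a NaN marker rather than an exception.  The default ν₀ is 43.3 MHz
(¹⁴N at a 600 MHz ¹H spectrometer), overridable per `FieldContext`.

Known data caveat: in the shipped nitrogen table the experimental P_Q
column is not arithmetically consistent with the tabulated shift
differences for the two weak-coupling sites (inverting δ_Q ≈ 183/197 ppm
gives ≈ 2.1–2.2 MHz, not the tabulated 2.5–2.6 MHz; the N10 row is
consistent), and the tabulated ¹⁴N shifts of N1/N7 are ambiguous between
sources.  The package exposes the formulas; neither the experimental P_Q
column nor the N7 row is used as a test oracle.

## Peak prediction

Peak lists are pure functions of (pair list, shift map, field); repeated
calls are byte-identical and peaks identical in (f1, f2, unordered pair)
are merged.  Intensity is represented only as a strong/weak class from the
internuclear distance (thresholds 2.6 / 1.2 / 1.3 Å for DQ / HETCOR /
HMQC) with the distance attached: quantitative intensities depend on
recoupling and CP dynamics that are out of scope.  Sites lacking a shift
are collected in a skip report, not fatal — partial assignment is the
normal state of a working analysis.

## Comparison statistics

Residuals are calc − exp throughout; RMSD = √(mean r²); the maximum
|residual| carries its site label, ties breaking to the first site in
label order.  A `table_precision` flag first rounds both columns to
1 decimal ppm, emulating statistics recomputed from printed tables.
Model ranking sorts by RMSD ascending and flags when the RMSD and
max-difference orderings disagree.  Rotamer-alternate experimental values
are stored in a separate column and never silently averaged into
comparisons.

## Synthetic generator

`generate_case` emulates the statistical structure of the comparison
problem, not the physics: sites are placed by rejection sampling
(minimum separation 0.8 Å) in a given cell; true shifts are drawn
uniformly per nucleus (¹H 0–15, ¹³C 10–180, ¹⁵N −300–0 ppm); shielding
tensors realise σ_iso = σ_ref_true − shift_true plus a random traceless
anisotropy in a random orientation; EFG tensors are built from drawn
(C_Q ∈ ±[2, 4.5] MHz, η ∈ [0, 1]) in the principal frame and rotated, so
tracelessness holds by construction; the "experimental" table is truth
plus independent Gaussian noise at σ = 0.2 / 0.1 / 5 ppm for ¹H / ¹³C /
¹⁵N, the stated accuracy of routine solid-state shift measurements.  One
seeded generator per case is consumed in a documented order (placement,
shifts, shielding orientations, EFG draws, noise), so a seed pins every
output byte-for-byte.

What passing tests therefore show: the plumbing (parsing, geometry,
referencing, inversion, statistics) is exact, and parameter recovery
behaves as √n statistics predict.  What they cannot show: that DFT
shieldings are accurate, or that shift patterns of real crystals (ring
currents, hydrogen-bond systematics, the temperature dependence of NH
shifts) are reproduced — the generator has no such structure by design.
`generate_hbond_motif` embeds a single D–H⋯A triplet with exactly the
requested (d_HA, angle) in a padded cell, optionally rigidly rotated,
giving a construction-inverse oracle for the hydrogen-bond search.

## Numerical choices and problem sizes

EFG trace tolerance 1e−6 a.u. (relative to the largest element);
round-trip tensor equality 1e−12; geometry oracle agreement 1e−9; η
clipped to [0, 1] against eigen-solver jitter.  Report precision follows
the conventions of the shipped tables: integer ppm for ¹⁴N-related
values, one decimal elsewhere; all comparisons run on unrounded values
unless table-precision emulation is requested.  The statistical property
tests use 200 seeded repetitions of a 25-site reference fit and a
60-site noise-tracking case; the acceptance script's synthetic stage uses
40 sites — sizes at which the √n bounds under test are comfortably
resolved while the whole suite runs in seconds.

## Known limitations

* No CSA conventions (span/skew/Haeberlen) — isotropic values only.
* No symmetry expansion, disorder or partial occupancy in structures.
* No lineshape or intensity simulation; peak positions only.
* The piecewise ¹³C referencing threshold behaviour within ±3 ppm of the
  boundary is a convention (first-pass classification), warned about, not
  physically resolved.
* Six calculated entries of the packaged cellulose table are
  reconstructed from the tabulated per-column maximum differences (see
  the CSV header); rebuilt statistics consequently carry a ~0.05 ppm
  quantisation floor relative to statistics computed from unrounded
  values.
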
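# Methods

This note records the models, conventions and numerical choices behind
`oxastack`, and what the synthetic fixtures do and do not establish.

## Structures, bonds and symmetry

All geometry downstream of `structure_io` is Cartesian angstroms;
fractional coordinates and symmetry operators never leave that module.
Parsing is delegated to gemmi (CIF, PDB, mmCIF, gzipped or not).

- **Bonds**: i–j bonded iff d ≤ r_cov(i) + r_cov(j) + 0.40 Å (Cordero
  covalent radii; the 0.40 Å tolerance is common crystallographic practice
  and configurable). Molecules are connected components of this graph.
- **Disorder**: CIF duplicate labels and PDB altlocs collapse to the
  highest-occupancy branch (PDB tie → altloc 'A'), so every file yields one
  deterministic conformer.
- **Symmetry images** carry a code (op_index, t1, t2, t3), identity
  = (0,0,0,0). Image enumeration brackets the needed lattice translations
  from the fractional bounding box plus a cutoff-derived margin
  (cutoff × row norms of the fractionalization matrix), then filters by
  actual distance with a k-d tree. A ring pair found as (i→j, code) is
  folded with its mate (j→i, inverse code) so each physical pair reports
  once.
- **vdW radii** are Bondi's (C 1.70, N 1.55, O 1.52, H 1.20, S 1.80 Å);
  the contact criterion is defined against this set.

## Ring perception and classification

Rings are chordless 5-/6-cycles of the bond graph that (a) fit a
least-squares plane with RMSD ≤ 0.10 Å and (b) have no member with more
than three non-hydrogen neighbours. The RMSD threshold accepts aromatic
rings (ideal: ~0) and rejects aliphatic ones (chair cyclohexane: 0.25 Å).
Aromaticity is therefore a planarity + saturation heuristic, not electron
counting — screening operates on ring identity and geometry only, which is
what the contact criteria need. Fused systems contribute one ring per
smallest cycle (naphthalene = two six-rings), matching per-ring contact
bookkeeping.

Plane fitting is an SVD of the centered member coordinates; the normal is
the smallest principal direction with its sign fixed (+z, ties toward +x
then +y) for reproducibility. Classification reads the element cycle:
O,N,C,N,C with N adjacent to O → 1,2,4-oxadiazole (roles O1,N2,C3,N4,C5);
O,C,N,N,C → 1,3,4-oxadiazole (roles O1,C2,N3,N4,C5); C6 → phenyl; C5N →
pyridine. Role assignment is rotation-invariant; symmetric patterns break
ties by the smallest atom-index sequence.

## Stacking descriptors

For centroids c_A, c_B and unit normals n_A, n_B:
R = |c_A − c_B|; h₁ = |(c_A − c_B)·n_B| (centroid A to plane B), h₂
symmetric; r₁ = distance in plane B from the projection of c_A to c_B, r₂
symmetric. Pairing r_i with h_i this way makes r_i² + h_i² = R² an exact
identity — the published descriptor tables' footnote wording is ambiguous
about the indexing, and this is the construction consistent with the
parallel-displaced rows (equal h and equal r on both sides, R = √(h²+r²)).
One published row is internally inconsistent with the identity under any
index pairing (likely typographic) and is excluded from assertions.

θ is the folded angle between the normals; φ is the folded angle between
the rings' in-plane reference axes, where the reference axis runs from the
centroid to the highest-priority atom (O > N > C, then lexicographic
label), both axes projected into ring A's plane. This reproduces φ = 0 for
inversion-related dimers (the axis maps to its antiparallel; folding
cancels it) and is well defined for heterocycles. For homocyclic rings
(phenyl) the reference atom is pure convention; such pairs carry a
`phi_convention_dependent` flag. Angles are computed with atan2 of
cross/dot, which is well conditioned near 0° and 90°.

Classification defaults (R ≤ 4.0 Å, θ ≤ 25°, min h ≥ 2.8 Å) bracket
typical reported parallel and parallel-displaced stacks; they are screening
defaults, not physical claims.

lp···π contacts require an N/O donor (different molecule, not a ring
member), a donor–ring-atom distance within ΣvdW + 0.1 Å for at least one
ring atom (the closest qualifying atom is reported, per-element limits),
and an elevation of the donor→centroid vector of at least 45° above the
ring plane. The elevation threshold separates above-plane lone-pair
geometry from the in-plane hydrogen-bonding regime.

## Contact screen

Queries are all atoms of perceived oxadiazole rings (each record carries
the atom's role for the census); partners are non-hydrogen atoms of any
π-ring of the allowed sizes (5/6). A contact qualifies when
d₁ ≤ ΣvdW + 0.5 Å and the two angles at the query atom between the contact
vector and its two in-ring bonds are both within [65°, 115°]; the same
window is enforced at the partner end, since the two-angle construction in
the surveyed criterion does not say at which end it is measured — demanding
both is the conservative reading. An alternative convention (contact vector
within 25° of the ring-plane normal) is available as a config switch.
Intramolecular (same-molecule, identity-image) pairs are excluded; crystal
images are included for periodic structures. CIFs with R-factor > 0.1 are
skipped with a warning (survey-quality filter).

Of several contacts between the same (structure, query ring, partner ring)
— including symmetry copies — only the shortest is kept for totals; census
totals count distinct (structure, query ring) per cell, per-role counts use
all qualifying contacts, and the homoleptic subtotal counts five-ring cells
whose partner is itself an oxadiazole.

For protein–ligand complexes, queries are oxadiazole rings among HETATM
ligand atoms and partners are aromatic side-chain rings (PHE/TYR/TRP/HIS)
or any other non-ligand π-ring; no symmetry expansion unless the file
carries a cell with more than the identity.

## Promolecular NCI

Atomic densities are modelled as ρ_A(r) = Σ_i c_i·exp(−r/ζ_i) (a.u.;
ζ in bohr), the functional form used for promolecular NCI analysis; the
package ships its own versioned three-term table for H–Ar. The fits are
shape fits, not normalized: 8π Σ c ζ³ lands within ±50% of each element's
electron count, which is sufficient because NCI diagnostics depend on the
local shape of ρ, |∇ρ| and the Hessian signature, all of which are exercised
by closed-form checks (single-shell RDG law, analytic vs finite-difference
derivatives, eigenvalue sign structure) rather than by absolute densities.

Gradient and Hessian are analytic per shell (f′ = −ρ/ζ, f″ = ρ/ζ²; the
Hessian combines radial and tangential curvature f′/r), never finite
differences; r is floored at 1e-12 bohr at nuclei and ρ at 1e-30 a.u.
before the 4/3 power. λ₂ comes from a closed-form trigonometric symmetric
3×3 eigen-solver (checked against LAPACK to 1e-10; exact degeneracies
resolve to the triple/double root, |λ₂| < 1e-30 maps to sign 0). Note that
the midpoint of an isolated homonuclear pair is a (3,−1)-type saddle at any
separation — tangential curvatures are negative — so sign(λ₂)ρ < 0 there;
positive-λ₂ (steric) points need a surrounding cage or ring, e.g. an
aromatic ring center.

Default grid: bounding box of the selected atoms + 3 Å margin at 0.15 Å
spacing. Cube files follow the standard volumetric layout (bohr, z-fastest);
the 2-D scatter keeps points with ρ ≤ 0.05 a.u. The isovalue for 3-D
rendering is left to the viewer.

## Diffusion association

D_corr(c) = D_obs(c) · D_ref(c_min)/D_ref(c) divides out bulk-viscosity
drift against the internal standard, referenced to the lowest measured
concentration. D₀ is the OLS intercept of D_corr against c (the
extrapolation model is not dictated by the underlying experiment; linear in
c is the default, linear in √c available), with the intercept's standard
error reported. N(c) = (D₀/D_obs)³ is exact in the Stokes–Einstein picture
of volume-proportional association; N is dimensionless and unit-free since
only ratios enter.

## Synthetic data: what it emulates, what it does not

Generators use regular polygons (C–C 1.39 Å / 1.36 Å for 6-/5-rings) with
the correct element cycles. Real heteroaromatic rings are slightly
irregular; none of the descriptors, criteria or censuses depend on ring
regularity, so the idealization is harmless for what the tests assert. The
default diffusion series spans 6–611 mM on a dilution ladder with a slope
planted so D₀/D_obs(611 mM) = 1.1241, i.e. N = 1.42 at the top — the
regime of weak association. All randomness flows through seeded
`numpy.random.default_rng` generators; fixtures are bit-reproducible.

The planted screening corpus (10 P1 crystals) contains 3 valid contacts
(C···C 3.85 Å along the local ring normal, angles 90/90), one distance
violator (3.95 Å, above the 3.90 Å C···C threshold) and one angle violator.
The angle violator is an in-plane exterior contact (both angles ≈ 126°):
a contact making small (<54°) angles with *both* in-ring bonds of a
pentagon carbon is geometrically impossible, and tilting to violate via a
single bond angle unavoidably brings the probe within van-der-Waals range
of the neighbouring ring atom, creating a genuine secondary contact — so
the exterior construction is the clean way to violate the angular window
while passing the distance test.

Passing on these fixtures shows the geometry, criteria and statistics are
implemented exactly; it does not validate ring perception against heavily
disordered or charged real-world structures, metal-coordinated rings, or
NCI against SCF densities (promolecular NCI is a topology surrogate, not
an energy model).

## Problem sizes and determinism

The test suite and the acceptance script run in seconds: 1000 pair specs
for the descriptor round trip, 200 tilted specs for the slip/height
identity, a 10-structure screening corpus, 200-point radial NCI samples and
50 random field points for derivative checks, 8-point diffusion series.
Grids for NCI examples use 0.25–0.5 Å spacing; production analyses would
use the 0.15 Å default. Every stochastic step takes an explicit seed; CLI
reruns are byte-identical.

## Known limitations

- No electronic aromaticity model; π-character is inferred from planarity.
- φ for phenyl/homocyclic rings is convention-dependent (flagged, not
  suppressed).
- Promolecular densities are spherical free-atom fits; no SCF, QTAIM
  critical-point search or interaction energies.
- The D₀ extrapolation model (linear in c) is an assumption; compare with
  the √c option when data allow.
- Database hit counts from licensed-corpus surveys are inherently
  release-dependent and are not reproduction targets; the screen operates
  on locally supplied files only.
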
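# Methods

This note records the conventions, default parameters and design choices
behind the pipeline, in the spirit of a model-description document: what is
computed, under which assumptions, and what the synthetic validation does
and does not demonstrate.

## Coordinate model and symmetry

Structures are lists of atom records (orthogonal Å coordinates, occupancy,
isotropic B, optional anisotropic tensor, altloc) plus a unit cell and a
space group. Orthogonalization follows the PDB convention (*a* along x,
*b* in the xy plane); fractional coordinates appear only inside symmetry
operations. Operators for P1, P2₁2₁2₁ and P4₃2₁2 — the triclinic,
orthorhombic and tetragonal settings relevant to lysozyme crystal forms —
are embedded as xyz-triplet tables; any other Hermann–Mauguin name is
resolved through gemmi. File I/O (PDB, minimal mmCIF, CCP4/MRC maps) also
goes through gemmi; the in-memory model is the package's own so geometry
code is independent of the I/O layer. Hydrogens are parsed but excluded
from all analysis; an atom with an unrecognized element symbol has its
element inferred from the atom name, with a warning.

The neighbor search transforms all atoms by every space-group operator
combined with lattice translations in {−1, 0, 1}³ and keeps images within
the query radius. This is exhaustive provided the radius is below half the
shortest cell edge, which a guard enforces; contact radii of interest
(≤ 6 Å) are far below protein cell edges (~37–80 Å). The search is verified
against an independent brute-force supercell expansion (exact hit-set
equality) in the test suite and in the acceptance script. Distances are
never measured across different altlocs of a partial-occupancy pair.

## Precision model

Two DPI variants are provided. The free-R form,
`sqrt(Natoms/Nrefl) · C^(−1/3) · Rfree · dmin`, is the default because it
stays defined for anisotropic refinements where the observations-minus-
parameters denominator of the original Cruickshank form approaches zero;
that form is provided too and raises an explicit "unstable" error when
N_obs ≤ N_params. `n_atoms` counts non-hydrogen atoms at any occupancy
(standard DPI practice) and is filled from the model when a statistics file
omits it.

Per-atom positional uncertainty uses the customary B-weighting
σᵢ = DPI·√(Bᵢ/⟨B⟩). This is a convention, not a derivation: published
per-bond esds rarely state their provenance, so the package validates its
propagation only against a Monte-Carlo oracle (10⁴ coordinate perturbation
draws reproduce the propagated distance and angle esds to well under 5%).
Angle esds use a central-difference Jacobian (step 10⁻⁵ Å) over the nine
coordinates with isotropic per-atom sigmas. Formatting follows the
crystallographic convention: the esd rounded to one significant figure,
shown in parentheses in units of the value's last quoted digit
(`2.25 (8)`, `41 (2)`).

## Reference data and contact classification

The shipped reference file carries small-molecule bond-distance ranges for
Re–N(imidazole), Re–O(carboxylate), Re–OH₂ and related fragments, the
κ²O,O′ chelate bite-angle range (59.4–59.8°), and two Re⋯Re separation
surveys (the *fac*-tricarbonyl-restricted set: 2.837–3.233 Å, mean 3.065,
sd 0.129, n = 15; and the all-oxidation-state set: 2.245–3.497 Å,
n = 1546). The van der Waals radii (Re 2.15, O 1.52, N 1.55, C 1.70 Å …)
are back-derived so the pairwise sums reproduce the protein-study values
Re+O = 3.67, Re+N = 3.70, Re+Re = 4.30 Å exactly; the file says so in its
provenance notes rather than citing per-element sources. Users can merge
overrides by range id.

Classification cutoffs, all configurable:

* **bond cutoff** = (tightest matching reference max) + 0.45 Å. The margin
  admits the long 2.5 Å Re–O bonds seen at C-terminal carboxylates while
  keeping a 2.62 Å approach in the next tier; when several reference ranges
  exist for a pair the tightest is used, since the loosest (aqua, 2.21 Å)
  would swallow genuine semi-coordination. No reference → covalent sum
  + 0.4 Å.
* **semi-coordination cutoff** = 2.9 Å.
* **vdW contact**: below the vdW sum.
* **borderline-vdW**: at or beyond the vdW sum but within 3 esd of it. The
  3-esd window is the usual crystallographic significance convention and
  reproduces the published treatment of a 3.96 (9) Å Re⋯N approach as "a
  van der Waals interaction within error" of the 3.7 Å sum (a 1-esd window
  would not).
* contacts under 1.2 Å are reported with an `implausible_distance` flag,
  never suppressed — mirroring how refined-but-unphysical contacts are
  reported in the literature rather than hidden.

## Denticity

Per residue image (same residue reached through the same symmetry
operator): no coordination bond but at least one closer-than-vdW approach →
`nonbinding_vicinity`; one bond and no other engaged donor →
`monodentate`; one bond plus a semi/vdW second donor at a QBA below 52° →
`anisobidentate`; two bonds at a QBA of 52° or more → `bidentate_chelate`;
three bonds → `tridentate`. The 52° threshold is the midpoint between the
largest observed anisobidentate QBA (47°) and the small-molecule chelate
minimum (59.4°); the two regimes are separated by ~12°, so the label is
robust to coordinate noise an order of magnitude larger than typical. A
semi/vdW second donor takes precedence over the bare "no second donor
within the semi cutoff" monodentate reading, because a 3.2–3.5 Å second
oxygen at a ~41° QBA is exactly the anisobidentate signature.

## Disorder and occupancy conventions

Same-element metal pairs closer than the all-oxidation-state minimum
(2.245 Å for Re) cannot be simultaneously present and are grouped (union
find, so grouping is symmetric and transitive) as alternate positions of
one fractionally disordered metal; the group's occupancy sum is flagged if
it exceeds 1 + 0.05. Pairs inside the reference M⋯M window are flagged
`possible_metal_metal_interaction`; pairs under the vdW sum,
`vdw_proximity`. Ligand atoms of the metal's own residue group are expected
to share the metal's occupancy (±0.05); zero occupancy is recognized as the
"chemically present but weakly visible" refinement convention and reported
separately rather than flagged.

## Density evidence

Peak heights are (value − map mean)/σ with σ the population standard
deviation over all voxels, so heights are invariant under linear rescaling;
whether published σ-levels are about-mean or about-zero is rarely stated,
and about-mean is documented here as the package convention. The default
estimator is the maximum grid value within 0.75 Å of the atom (refined
centers rarely sit on the peak voxel); exact trilinear interpolation
(`at_point`) is available for strictness. Sites below 3.0σ — the customary
display contour for anomalous difference maps — are flagged
`weak_evidence`. Map and model cells must agree within 1%.

## Synthetic data

The generator plants the binding modes the pipeline must distinguish:
monodentate imidazole (Re–N 2.20 Å), anisobidentate carboxylate (2.15 and
3.30 Å arms; QBA derived from a 2.20 Å carboxylate O⋯O separation via the
law of cosines, ≈ 41.2°, or given explicitly), a κ²O,O′ chelate (59.6°
bite), a 3.30 Å vicinity contact, a 1.5 Å disorder pair (occupancies
0.25/0.15) and a nonbinding metal. Each coordinated metal carries three
facial carbonyls and, for the imidazole template, two aqua ligands at the
metal's occupancy; one template plants a zero-occupancy carbonyl to
exercise the occupancy-convention checks. Default occupancies (0.83, 0.42,
0.60, 0.30, 0.25/0.15, 0.40) span the realistic partial-occupancy regime.
The default cell is orthorhombic P2₁2₁2₁, 40 × 80 × 80 Å; anchors are laid
out so that neither direct neighbors nor symmetry images approach a site
within contact range (asserted by test). Coordinate noise is i.i.d.
Gaussian per component; ground truth records the pre-noise geometry and
regenerates bit-identically from (specs, seed). Infeasible geometry
requests (arm lengths that admit no triangle with the carboxylate O⋯O
separation) are rejected before any atoms are emitted.

Scaffold realism is deliberately minimal — a schematic poly-alanine chain,
no Ramachandran validity, no solvent model — because downstream stages
consume only geometry, occupancies and B factors. Consequently the passing
recovery tests demonstrate correctness of the measurement and
classification machinery, not robustness to real-data pathologies such as
model bias, radiation damage, or correlated coordinate error.

Synthetic maps are white Gaussian background noise plus a Gaussian peak
(width 0.5 Å) at each metal. Requested peak heights are in σ units of the
final map, which creates a subtlety: with white noise, an a-priori
amplitude realizes the requested normalized height only in expectation —
the noise draw at the peak voxel contributes ~1σ of irreducible error. The
generator therefore calibrates each amplitude against the realized map (two
fixed-point passes using the default local-max estimator), so planted
heights are achieved to well within 0.5σ. This makes the generator's
ground truth exact by construction, which is the property the recovery
tests need; it does not emulate the noise statistics of real anomalous
difference maps.

## Validation problem sizes

The default validation runs 100 synthetic structures (~80 atoms, 7 metal
sites each) at 0.03 Å noise for parameter recovery, 21 random fixtures
across the three space groups for the neighbor-search oracle, 10⁴ draws for
each Monte-Carlo esd check, and 15 synthetic maps (30 Å P1 cells, 0.5 Å
grid) for peak recovery — sizes chosen so the whole suite completes in
seconds while keeping every aggregate statistic stable to well inside its
tolerance. Distance recovery is judged as RMSE against the planted values
(the per-measurement bound is σ√2 for two independently perturbed
endpoints); QBA recovery likewise as an aggregate (RMSE and 95th
percentile within 3°), since the propagated per-QBA esd at the planted
geometries is ~1.2–1.4°, which makes a hard 3° ceiling on the maximum of
hundreds of draws a statistical impossibility rather than a meaningful
requirement.

## Known limitations

* mmCIF support is minimal (atom_site, cell, symmetry categories); no
  dictionary validation.
* Axis-setting differences between processing conventions are not
  normalized at parse time; the superposition engine instead searches the
  24 proper axis relabelings when asked (`try_axis_relabeling`), which
  covers models of the same crystal indexed with permuted cell axes.
* Superposition matching is by identical (chain, residue number, atom
  name); no sequence alignment.
* The pipeline measures and classifies; it does not re-refine occupancies,
  synthesize maps from structure factors, or handle anomalous scattering
  factors.
* Reference ranges are a static snapshot; there is no live small-molecule
  database querying.
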
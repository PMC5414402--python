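# metalsites

Symmetry-aware characterization of metal coordination environments in
refined protein crystal structures, built for the kind of question raised by
radiopharmaceutical fragment screening: where does a metal synthon such as
*fac*-[Re(CO)₃]⁺ bind on a protein surface, with what geometry, and how sure
can we be of each number?

Given a refined model (PDB or minimal mmCIF) the pipeline

* finds the metal atoms and builds each one's contact sphere, expanding over
  all space-group operators and ±1 lattice translations so that
  crystal-packing contacts are not missed;
* measures metal–donor distances and **quasi bite angles** (QBA) — the angle
  at the metal between two candidate donor atoms of the same residue — which
  separate true κ²O,O′ chelation (bite ≈ 59–60°) from monodentate binding
  with a proximal second donor (QBA ≈ 34–47°);
* propagates coordinate uncertainty from the **Cruickshank diffraction
  precision index** (DPI) to per-bond and per-angle esds, printed in the
  crystallographic `2.25 (8)` style;
* classifies every contact against shipped small-molecule (CSD-derived)
  reference ranges on a tiered scale — coordination bond, semi-coordination,
  van der Waals contact, borderline-vdW, nonbonded — and assigns a
  per-residue denticity label (monodentate, anisobidentate, bidentate
  chelate, tridentate, nonbinding vicinity);
* groups fractionally disordered metal positions (same-element pairs closer
  than any chemically known M⋯M separation), checks occupancy conventions
  for complex ligands, and optionally scores each site against an
  anomalous-difference density map in map-sigma units.

A synthetic-data module generates crystal structures and maps with fully
known planted geometry, so every stage is testable by construct-and-recover
without any downloads.

## The quantities at the core

For refinement statistics (free R factor, resolution d_min, completeness C,
N_atoms, N_reflections) the DPI is

    DPI = sqrt(N_atoms / N_refl) · C^(−1/3) · R_free · d_min        [Å]

with the original observations-minus-parameters variant also available (and
refused when N_obs − N_params is not safely positive). Per-atom positional
uncertainties are scaled by B-factor weighting, σᵢ = DPI·√(Bᵢ/⟨B⟩),
combined in quadrature for distances, and pushed through a first-order
Jacobian for angles.

The QBA for donors D₁, D₂ of one residue bound to metal M is the angle
∠(D₁–M–D₂); it is tied to the donor–donor separation by the law of cosines,
which the package uses as an internal cross-check
(`implied_third_side(d1, d2, θ)`).

## Worked example

```python
from metalsites import (generate_structure, characterize,
                        RefinementStats, format_with_esd)

s, truth = generate_structure(noise_sigma=0.02, seed=11)
stats = RefinementStats(r_free=0.20, dmin=1.3, completeness=0.999,
                        n_reflections=60000)
report = characterize(s, stats=stats)
print(f"DPI = {report.dpi:.4f} A")
for site in report.sites:
    for reskey, label in site.denticity.items():
        print(f"{site.site_id:>14s}  {reskey:<8s} {label}")
```

prints

```
DPI = 0.0096 A
    RRE200X:RE  HIS10A   monodentate
    RRE202X:RE  ASP12A   anisobidentate
    RRE204X:RE  GLU14A   bidentate_chelate
    RRE206X:RE  GLU16A   nonbinding_vicinity
```

(the DPI is small here because the synthetic structure has only 81 atoms).
The planted aspartate site was generated with one 2.15 Å Re–O bond and a
3.30 Å second-oxygen contact; its measured QBA comes back as
`41.0 (4)` degrees — an anisobidentate carboxylate, not a chelate — and the
planted glutamate chelate (59.6° bite) is labelled `bidentate_chelate`.
Two planted Re positions 1.5 Å apart are grouped as alternate positions of
one fractionally disordered metal (occupancy sum 0.4 ≤ 1):

```
disorder group: ['RRE208X:RE', 'RRE209X:RE'] occupancy sum 0.4
```

The same analysis runs from the shell:

```sh
metalsites synth --out fixture --seed 11 --noise 0.02
metalsites characterize --model fixture/synthetic.pdb \
    --map fixture/synthetic_anomalous.ccp4 --out report
metalsites dpi --stats table1.json
metalsites compare --model a.pdb --second-model b.pdb --out overlay
```

`characterize` writes `report.json` (full site records) and `contacts.tsv`
(one row per classified contact); logs go to stderr only.

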
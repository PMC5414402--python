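{
  "version": "1.0",
  "description": "Element radii and small-molecule reference ranges for fac-[M(CO)3]+ coordination analysis. Distance ranges and Re...Re statistics are distilled from published CSD surveys of rhenium tricarbonyl chemistry; radii are back-derived so that the pairwise sums reproduce the van der Waals sums used in the protein study (Re+O 3.67, Re+N 3.70, Re+Re 4.30 A) and are not per-element literature citations.",
  "radii": {
    "source": "back-derived vdW set anchored to Re+O=3.67, Re+N=3.70, Re+Re=4.30",
    "vdw": {
      "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
      "P": 1.80, "CL": 1.75, "BR": 1.85, "RE": 2.15, "TC": 2.15
    },
    "covalent": {
      "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
      "P": 1.07, "CL": 1.02, "BR": 1.20, "RE": 1.51, "TC": 1.47
    }
  },
  "ranges": [
    {
      "id": "re_n_imidazole_fac",
      "descriptor": "Re-N(imidazole), fac-tricarbonyl complexes",
      "metal": "RE", "partner": "N", "kind": "distance",
      "min": 2.174, "max": 2.197,
      "provenance": "CSD fac-[Re(CO)3(N-imidazole)] complexes, 2.174(4)-2.197(5) A"
    },
    {
      "id": "re_o_carboxylate",
      "descriptor": "Re-O(carboxylate), aspartate-like fragments",
      "metal": "RE", "partner": "O", "kind": "distance",
      "min": 2.138, "max": 2.149,
      "provenance": "CSD refcodes CEJSOB (2.138(2) A avg) and UDENAU (2.149(4) A)"
    },
    {
      "id": "re_o_aqua",
      "descriptor": "Re-OH2, fac-[Re(CO)3(H2O)3]+",
      "metal": "RE", "partner": "O", "kind": "distance",
      "min": 2.171, "max": 2.21,
      "provenance": "small-molecule fac-[Re(CO)3(H2O)3]+ aqua distances 2.171(5)-2.21(1) A"
    },
    {
      "id": "re_o_glutamate",
      "descriptor": "Re-O, kappa-N,O glutamic acid complex",
      "metal": "RE", "partner": "O", "kind": "distance",
      "min": 2.163, "max": 2.163,
      "provenance": "CSD refcode EXIWUD, Re-O 2.163(4) A"
    },
    {
      "id": "re_o_leucine_reV",
      "descriptor": "Re-O(leucine), rhenium(V) complex",
      "metal": "RE", "partner": "O", "kind": "distance",
      "min": 2.12, "max": 2.12,
      "provenance": "CSD refcode LOPTOZ, Re-O 2.12(1) A"
    },
    {
      "id": "re_n_leucine_reV",
      "descriptor": "Re-N(leucine), rhenium(V) complex",
      "metal": "RE", "partner": "N", "kind": "distance",
      "min": 2.22, "max": 2.22,
      "provenance": "CSD refcode LOPTOZ, Re-N 2.22(3) A"
    },
    {
      "id": "bite_angle_k2_OO",
      "descriptor": "kappa2-O,O' carboxylate chelate bite angle",
      "metal": "RE", "partner": "O", "kind": "angle",
      "min": 59.4, "max": 59.8,
      "provenance": "four-coordinated kappa2-O,O' complexes, 59.4(1)-59.8(2) deg"
    },
    {
      "id": "re_re_fac_tricarbonyl",
      "descriptor": "Re...Re separations, fac-[Re(CO)3]+ fragment",
      "metal": "RE", "partner": "RE", "kind": "metal_metal",
      "min": 2.837, "max": 3.233, "mean": 3.065, "sd": 0.129, "n": 15,
      "provenance": "CSD/Mogul survey restricted to the fac-[Re(CO)3]+ fragment (15 hits)"
    },
    {
      "id": "re_re_all_oxidation_states",
      "descriptor": "Re...Re separations, all oxidation states and modes",
      "metal": "RE", "partner": "RE", "kind": "metal_metal",
      "min": 2.245, "max": 3.497, "n": 1546,
      "provenance": "CSD survey of all Re...Re interactions (1546 hits); extremes GUVTUO (short) and PORYIE (long)"
    }
  ]
}
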
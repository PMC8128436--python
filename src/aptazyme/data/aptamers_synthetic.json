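{
  "comment": "SYNTHETIC placeholder aptamers. The published tetracycline, chloramphenicol and folinic acid aptamer sequences are not bundled; these entries are structurally plausible stand-ins (terminal 3-bp clamp, annotated binding bulge, internal hairpin) so the design pipeline can be exercised end to end. Replace with verified sequences before any wet-lab use.",
  "aptamers": [
    {
      "name": "tetracycline",
      "ligand": "tetracycline",
      "full_sequence": "GGCUAAAUGGGCGAAAGCCCAAGCC",
      "full_structure": "(((.....((((....))))..)))",
      "binding_bulge": [3, 8],
      "allowed_positions": ["I", "II"],
      "provenance": "synthetic placeholder"
    },
    {
      "name": "chloramphenicol",
      "ligand": "chloramphenicol",
      "full_sequence": "GGCAGAAUCCGGUUCGCCGGAUGCC",
      "full_structure": "(((.....((((....))))..)))",
      "binding_bulge": [3, 8],
      "allowed_positions": ["I", "II"],
      "provenance": "synthetic placeholder"
    },
    {
      "name": "folinic_acid",
      "ligand": "folinic acid",
      "full_sequence": "GGCGUAAGGCAAGAUUUCUUGCAGCC",
      "full_structure": "(((.....(((((....))))).)))",
      "binding_bulge": [3, 8],
      "allowed_positions": ["I", "II"],
      "provenance": "synthetic placeholder"
    }
  ]
}
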
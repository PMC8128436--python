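{
  "comment": "Small-molecule RNA aptamers with literature-derived core sequences, written as full aptamer (terminal closing helix included) + dot-bracket + 0-based half-open binding-bulge annotation. The terminal helix is a minimal 3-bp clamp standing in for the published closing stem; grafting removes it anyway.",
  "aptamers": [
    {
      "name": "theophylline",
      "ligand": "theophylline",
      "full_sequence": "GGCAUACCAGCCGAAAGGCCCUUGGCAGCGCC",
      "full_structure": "(((......(((((.......)))))...)))",
      "binding_bulge": [3, 9],
      "allowed_positions": ["I", "II"],
      "provenance": "literature-derived (Jenison-type core as used in ribozyme switches)"
    },
    {
      "name": "neomycin",
      "ligand": "neomycin",
      "full_sequence": "GGCGCUUGUCCUUUAAUGGUCCAGUCGCC",
      "full_structure": "(((......((......)).......)))",
      "binding_bulge": [3, 9],
      "allowed_positions": ["I", "II"],
      "provenance": "literature-derived (Weigand/Suess N1 core)"
    }
  ]
}
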
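{
  "name": "sTRSV",
  "comment": "Satellite RNA of tobacco ringspot virus hammerhead ribozyme scaffold (literature-derived). Segment order follows the type-III hammerhead topology; loops I and II are inserted at the LOOP1/LOOP2 slots. Spacer segments are empty so the assembled native construct equals the 52-nt literature ribozyme; edit them to add cassette spacers.",
  "provenance": "literature-derived",
  "order": ["spacer5", "stem3_5arm", "stem1_5arm", "LOOP1", "stem1_3arm", "core", "stem2_5arm", "LOOP2", "stem2_3arm", "core2", "stem3_3arm", "spacer3"],
  "segments": {
    "spacer5": "",
    "stem3_5arm": "GCUGUC",
    "stem1_5arm": "ACCGGA",
    "stem1_3arm": "UCCGGU",
    "core": "CUGAUGA",
    "stem2_5arm": "GUCC",
    "stem2_3arm": "GGAC",
    "core2": "GAAA",
    "stem3_3arm": "CAGC",
    "spacer3": ""
  },
  "default_stem1_len": 6,
  "default_stem2_len": 4,
  "native_loop1": "UGUGCUU",
  "native_loop2": "GUGA",
  "native_full_sequence": "GCUGUCACCGGAUGUGCUUUCCGGUCUGAUGAGUCCGUGAGGACGAAACAGC"
}
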
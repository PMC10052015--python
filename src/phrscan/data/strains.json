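{
  "comment": "Study strains: habitat class of the isolation site and whether a phr2 photolyase gene is present in the genome. Habitat classes: surface (brine/salt crust exposed to sunlight), sediment (light-deprived lake bottom), subsurface (Permian halite mine).",
  "strains": {
    "NRC-1":   {"species": "Halobacterium sp. NRC-1",          "habitat": "surface",    "phr2_present": true},
    "BOL4-2":  {"species": "Halobacterium sp. BOL4-2",         "habitat": "surface",    "phr2_present": true},
    "GSL-19":  {"species": "Halobacterium sp. GSL-19",         "habitat": "surface",    "phr2_present": true},
    "JOR-1":   {"species": "Salarchaeum sp. JOR-1",            "habitat": "surface",    "phr2_present": true},
    "BOL3-1":  {"species": "Halorubrum sp. BOL3-1",            "habitat": "surface",    "phr2_present": true},
    "Hla":     {"species": "Halorubrum lacusprofundi",         "habitat": "sediment",   "phr2_present": true},
    "BOL5-1":  {"species": "Haloterrigena salifodinae BOL5-1", "habitat": "subsurface", "phr2_present": true},
    "BOL6-1":  {"species": "Natrinema pallidum BOL6-1",        "habitat": "subsurface", "phr2_present": true},
    "BOL5-4":  {"species": "Natrinema versiforme BOL5-4",      "habitat": "subsurface", "phr2_present": false}
  }
}
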
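{
 "comment": "Five-state condensation energy profiles, kJ/mol relative to separated monomers (state 1 = 0). Per-pair values are representative placements inside the text-stated ranges (pair binding -25 to -100, bound-water product near -50, water removal near +200, glycol -40/290), hence approximate=true on every record.",
 "species": [
  {"name": "Gly", "atom_count": 10, "mass_u": 75.07, "kind": "amino_acid"},
  {"name": "Ala", "atom_count": 13, "mass_u": 89.09, "kind": "amino_acid"},
  {"name": "Ser", "atom_count": 14, "mass_u": 105.09, "kind": "amino_acid"},
  {"name": "Pro", "atom_count": 17, "mass_u": 115.13, "kind": "amino_acid"},
  {"name": "Ile", "atom_count": 22, "mass_u": 131.17, "kind": "amino_acid"},
  {"name": "Leu", "atom_count": 22, "mass_u": 131.17, "kind": "amino_acid"},
  {"name": "Asn", "atom_count": 17, "mass_u": 132.12, "kind": "amino_acid"},
  {"name": "Asp", "atom_count": 16, "mass_u": 133.10, "kind": "amino_acid"},
  {"name": "Glu", "atom_count": 19, "mass_u": 147.13, "kind": "amino_acid"},
  {"name": "Lys", "atom_count": 24, "mass_u": 146.19, "kind": "amino_acid"},
  {"name": "Phe", "atom_count": 23, "mass_u": 165.19, "kind": "amino_acid"},
  {"name": "ethylene_glycol", "atom_count": 10, "mass_u": 62.07, "kind": "glycol"},
  {"name": "water", "atom_count": 3, "mass_u": 18.02, "kind": "water"},
  {"name": "Gly-Gly", "atom_count": 17, "mass_u": 132.12, "kind": "polymer"},
  {"name": "Gly-Ala", "atom_count": 20, "mass_u": 146.14, "kind": "polymer"}
 ],
 "profiles": [
  {"pair": ["Glu", "Ala"], "conformer": 1, "e_pair": -70.0, "e_ts": -15.0, "e4": -55.0, "e5": 145.0, "approximate": true},
  {"pair": ["Glu", "Ala"], "conformer": 2, "e_pair": -60.0, "e_ts": 10.0, "e4": -50.0, "e5": 150.0, "approximate": true},
  {"pair": ["Asp", "Ile"], "conformer": 1, "e_pair": -65.0, "e_ts": -5.0, "e4": -52.0, "e5": 160.0, "approximate": true},
  {"pair": ["Ser", "Leu"], "conformer": 1, "e_pair": -55.0, "e_ts": 25.0, "e4": -48.0, "e5": 148.0, "approximate": true},
  {"pair": ["Ser", "Leu"], "conformer": 2, "e_pair": -45.0, "e_ts": 40.0, "e4": -42.0, "e5": 168.0, "approximate": true},
  {"pair": ["Asn", "Pro"], "conformer": 1, "e_pair": -75.0, "e_ts": 50.0, "e4": -58.0, "e5": 142.0, "approximate": true},
  {"pair": ["Ile", "Gly"], "conformer": 1, "e_pair": -50.0, "e_ts": 30.0, "e4": -45.0, "e5": 160.0, "approximate": true},
  {"pair": ["Lys", "Phe"], "conformer": 1, "e_pair": -90.0, "e_ts": 120.0, "e4": -62.0, "e5": 150.0, "approximate": true},
  {"pair": ["Phe", "Gly"], "conformer": 1, "e_pair": -60.0, "e_ts": 150.0, "e4": -50.0, "e5": 145.0, "approximate": true},
  {"pair": ["Phe", "Gly"], "conformer": 2, "e_pair": -40.0, "e_ts": 180.0, "e4": -40.0, "e5": 165.0, "approximate": true},
  {"pair": ["Ala", "Ala"], "conformer": 1, "e_pair": -55.0, "e_ts": 210.0, "e4": -48.0, "e5": 152.0, "approximate": true},
  {"pair": ["Ala", "Ala"], "conformer": 2, "e_pair": -30.0, "e_ts": 250.0, "e4": -35.0, "e5": 185.0, "approximate": true},
  {"pair": ["Gly", "Gly"], "conformer": 1, "e_pair": -60.0, "e_ts": 200.0, "e4": -50.0, "e5": 150.0, "approximate": true},
  {"pair": ["Ala", "Gly"], "conformer": 1, "e_pair": -65.0, "e_ts": 170.0, "e4": -53.0, "e5": 147.0, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 1, "e_pair": -40.0, "e_ts": 290.0, "e4": 20.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 2, "e_pair": -35.0, "e_ts": 280.0, "e4": 25.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 3, "e_pair": -45.0, "e_ts": 300.0, "e4": 15.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 4, "e_pair": -30.0, "e_ts": 270.0, "e4": 30.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 5, "e_pair": -40.0, "e_ts": 0.0, "e4": 35.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 6, "e_pair": -38.0, "e_ts": 5.0, "e4": 28.0, "e5": null, "approximate": true},
  {"pair": ["ethylene_glycol", "ethylene_glycol"], "conformer": 7, "e_pair": -42.0, "e_ts": 2.0, "e4": 22.0, "e5": null, "approximate": true},
  {"pair": ["Gly-Gly", "Gly-Ala"], "conformer": 1, "e_pair": -60.0, "e_ts": 45.0, "e4": -55.0, "e5": 145.0, "approximate": true}
 ]
}
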
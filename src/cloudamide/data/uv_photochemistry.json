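{
 "comment": "Ultraviolet photodestruction constants for free amino acids (first-order half-lives by radiation environment) and measured destruction quantum efficiencies of small peptides under deep-UV exposure.",
 "uv_environments": [
  {"class": "DISM", "half_life_yr": 300.0},
  {"class": "DC", "half_life_yr": 3.0e7}
 ],
 "peptides": [
  {"species": "Gly-Trp", "wavelength_nm": 145.0, "qe": 0.013},
  {"species": "Gly-Gly", "wavelength_nm": 206.0, "qe": 0.022}
 ]
}
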
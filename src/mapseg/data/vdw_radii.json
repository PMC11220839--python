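{
  "_comment": "Van der Waals radii in Angstrom. Main-group values from Bondi (1964); alkali/alkaline-earth and transition metals from the Alvarez (2013) consistent set, rounded to 2 decimals. Swappable: pass a custom table to read_model(radii=...).",
  "H": 1.2,
  "D": 1.2,
  "C": 1.7,
  "N": 1.55,
  "O": 1.52,
  "F": 1.47,
  "P": 1.8,
  "S": 1.8,
  "CL": 1.75,
  "BR": 1.85,
  "I": 1.98,
  "SE": 1.9,
  "B": 1.92,
  "SI": 2.1,
  "NA": 2.27,
  "MG": 1.73,
  "K": 2.75,
  "CA": 2.31,
  "MN": 2.05,
  "FE": 2.04,
  "CO": 2.0,
  "NI": 1.97,
  "CU": 1.96,
  "ZN": 2.01,
  "CD": 2.18,
  "HG": 2.23,
  "AU": 2.32,
  "PT": 2.29,
  "W": 2.18,
  "MO": 2.17
}
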
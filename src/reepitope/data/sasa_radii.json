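{
  "comment": "van der Waals radii (Angstrom) for solvent-accessible surface area, element-keyed. Values follow the Chothia (1976) / NACCESS convention for protein heavy atoms.",
  "radii": {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98
  },
  "default": 1.70,
  "probe_radius": 1.4
}
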
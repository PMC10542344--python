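{
  "comment": "Black & Mould (1991) residue hydrophobicity, normalized to [0,1]. Aggregation-propensity scoring re-centres the scale at glycine so that polar residues contribute negatively and hydrophobic residues positively.",
  "scale": {
    "A": 0.616, "R": 0.000, "N": 0.236, "D": 0.028, "C": 0.680,
    "Q": 0.251, "E": 0.043, "G": 0.501, "H": 0.165, "I": 0.943,
    "L": 0.943, "K": 0.283, "M": 0.738, "F": 1.000, "P": 0.711,
    "S": 0.359, "T": 0.450, "W": 0.878, "Y": 0.880, "V": 0.825
  },
  "center_on": "G"
}
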
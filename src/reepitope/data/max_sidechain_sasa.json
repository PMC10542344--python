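{
  "comment": "Fully exposed side-chain solvent-accessible surface areas (Angstrom^2) of residue X in an extended Gly-X-Gly context, after Miller et al. (1987). Used as the denominator of exposure ratios. Glycine has no side chain; its entry is a placeholder so the ratio is defined (glycine's centred hydrophobicity is zero, so its contribution vanishes regardless).",
  "sasa": {
    "A": 67.0, "R": 196.0, "N": 113.0, "D": 106.0, "C": 104.0,
    "Q": 144.0, "E": 138.0, "G": 25.0, "H": 151.0, "I": 140.0,
    "L": 137.0, "K": 167.0, "M": 160.0, "F": 175.0, "P": 105.0,
    "S": 80.0, "T": 102.0, "W": 217.0, "Y": 187.0, "V": 117.0
  }
}
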
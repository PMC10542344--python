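{
 "name": "A_11.1",
 "comment": "First-generation focused library: 16 positions in CDRs L1, L2, L3 and H3, each allowing the template residue or one guide residue, plus one optional single-residue insertion in H3 (131,072 protein variants). Template sequences and guide-residue choices are illustrative synthetic stand-ins; edit this file to encode a real design.",
 "template": {
  "H": "EVQLVQSGAEVKKPGESLKISCKGSGYSFTSYWIGWVRQMPGKGLEWMGIIYPGDSDTRYSPSFQGQVTISADKSISTAYLQWSSLKASDTAMYYCARQYYGSSYWYFDLWGRGTLVTVSS",
  "L": "EIVLTQSPATLSLSPGERATLSCRASQSVSSYLAWYQQKPGQAPRLLIYDASNRATGIPARFSGSGSGTDFTLTISSLEPEDFAVYYCQQRSNWPPLTFGGGTKVEIK"
 },
 "diversities": [
  {
   "chain": "L",
   "position": 27,
   "allowed": "QE"
  },
  {
   "chain": "L",
   "position": 29,
   "allowed": "VI"
  },
  {
   "chain": "L",
   "position": 31,
   "allowed": "ST"
  },
  {
   "chain": "L",
   "position": 33,
   "allowed": "LF"
  },
  {
   "chain": "L",
   "position": 50,
   "allowed": "DN"
  },
  {
   "chain": "L",
   "position": 53,
   "allowed": "ND"
  },
  {
   "chain": "L",
   "position": 91,
   "allowed": "RK"
  },
  {
   "chain": "L",
   "position": 93,
   "allowed": "ND"
  },
  {
   "chain": "L",
   "position": 95,
   "allowed": "PA"
  },
  {
   "chain": "L",
   "position": 97,
   "allowed": "LF"
  },
  {
   "chain": "H",
   "position": 99,
   "allowed": "QE"
  },
  {
   "chain": "H",
   "position": 100,
   "allowed": "YW"
  },
  {
   "chain": "H",
   "position": 102,
   "allowed": "GA"
  },
  {
   "chain": "H",
   "position": 104,
   "allowed": "ST"
  },
  {
   "chain": "H",
   "position": 106,
   "allowed": "WY"
  },
  {
   "chain": "H",
   "position": 108,
   "allowed": "FY"
  }
 ],
 "insertions": [
  {
   "chain": "H",
   "after_position": 105,
   "residues": "G",
   "optional": true
  }
 ]
}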
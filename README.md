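# reepitope

A computational toolkit for **antibody re-epitoping**: taking a well-behaved
template antibody and engineering it — with a minimal number of mutations —
to bind a *new* antigen at a predictable epitope. The package covers the
computational side of that workflow for structural bioinformaticians and
antibody engineers:

- **Interface analysis** — paratopes and epitopes as residues with any heavy
  atom within 5 Å of the partner, buried surface area (ΔSASA, Shrake–Rupley),
  a Lawrence–Colman-style shape-complementarity statistic S<sub>c</sub>, and
  cross-complex paratope conservation (shared positions, identical side
  chains, germline side chains) under IMGT numbering.
- **Antibody annotation** — IMGT numbering by alignment transfer from
  numbered germline references, CDR membership (CDR1 27–38, CDR2 56–65,
  CDR3 105–117), germline V-gene assignment with per-position
  germline/mutated flags.
- **Focused library design** — per-position allowed-residue sets, optional
  insertions and degenerate codons (e.g. NNS); exact library sizes by closed
  form *and* enumeration; identity-to-template statistics.
- **Docking-pose classification** (HexRF-style) — rigid-body decoy
  generation around a native complex, fnat labelling, interface
  featurization (surface size, amino-acid composition, specific
  interactions, engine-score distribution) and a grouped-cross-validated
  random-forest discriminator that ranks candidate template antibodies
  against a target antigen.
- **Pairwise epitope prediction** (PpRF-style) — curation of a training
  corpus (resolution < 3.0 Å, protein antigens, redundancy collapse at
  >95 % antigen / >85 % antigen-binding-region identity), per-chain random
  forests over antibody-position × antigen-residue pairs with fourfold
  grouped cross-validation, and epitope-patch prediction from the
  top-scoring pairs.
- **Aggregation hotspots** — an open reconstruction of spatial aggregation
  propensity (SAP): exposure-weighted, glycine-centred hydrophobicity summed
  over a 5 Å neighbourhood, with polarity-increasing substitution
  suggestions for the top-ranked surface positions.

A `synthetic` module generates deterministic toy complexes with planted
contact sets, planted-signal training corpora and synthetic germlines, so
every stage is testable offline with no downloads.

## Worked example

The first-generation focused library varies 16 CDR positions (L1, L2, L3,
H3) between the template residue and one structurally chosen guide residue,
plus one optional single-residue insertion in H3. The shipped example spec
(`reepitope/data/a11_1_library.json`; the varied residues are illustrative
and user-editable):

```bash
$ reepitope library stats --spec src/reepitope/data/a11_1_library.json
{
 "name": "A_11.1",
 "size": 131072,
 "min_identity": 92.6087,
 "max_identity": 100.0,
 "mean_identity": 96.2968
}
```

`size` is 2¹⁶ × 2 = **131,072** distinct protein variants (16 two-state
positions; the optional insertion contributes a factor of two). Every
variant stays **> 92 % identical** to the ~230-residue Fv template — the
library is focused, not randomized.

Interface analysis on a generated fixture:

```bash
$ reepitope fixtures toy-complex --out demo.pdb --planted 1,3,5 --seed 7
wrote demo.pdb (48 atoms, 3 planted contacts)
$ reepitope contacts --structure demo.pdb --side-a A --side-b B --cutoff 5.0
chain_a	res_a	chain_b	res_b
A	2	B	2
A	4	B	4
A	6	B	6
```

The three reported residue pairs are exactly the planted ground-truth
contacts (the sidecar `demo.pdb.truth.json` carries them machine-readably).

## Layout

```
src/reepitope/
  structure.py    PDB/mmCIF loading (gemmi), chain selection, sequences
  annotation.py   IMGT numbering, germline assignment and flags
  interface.py    contacts, paratope/epitope, ΔSASA, Sc, conservation
  sasa.py         Shrake–Rupley sampler shared by interface/SAP/pairwise
  library.py      LibrarySpec, sizes, enumeration, codons, identity stats
  pose.py         decoys, fnat, pose features, forest training, panel screen
  pairwise.py     corpus curation, pair features, grouped CV, epitope patch
  sap.py          spatial aggregation propensity and hotspot ranking
  synthetic.py    deterministic fixture generators with planted ground truth
  workflows.py    end-to-end cross-complex conservation analysis
  cli.py          `reepitope` command-line entry point
docs/methods.md   model and parameter documentation
```
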
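# Methods

This note documents the models, conventions and parameter choices behind
`reepitope`, in the order a re-epitoping analysis uses them.

## Structure model

Structures are reduced at load time to the content interface geometry is
defined on: amino-acid polymer residues only (waters, ions, buffer
components and other ligands are dropped), heavy atoms only (hydrogens are
dropped even when present — deposited X-ray models are heavy-atom models,
and all contact definitions below are heavy-atom definitions). Alternate
locations are resolved per (residue, atom name) to the highest-occupancy
conformer; ties prefer altloc `A`, then lexicographic order. Author residue
numbering with insertion codes is the canonical residue coordinate system;
1-based sequence indices are derived, never primary. No symmetry expansion
or assembly generation is performed: the asymmetric-unit content as
deposited is the working unit, and crystallographically redundant
interfaces are reached by explicit chain selection.

## Contacts, paratope and epitope

A residue pair is a contact when **any** heavy-atom pair across the two
sides lies at distance ≤ cutoff, inclusive, with cutoff **5.0 Å** by
default. No per-atom-type radii enter the definition; anything finer is not
supported by the convention this implements. Contacts are computed with a
k-d tree but *defined* by the exhaustive pairwise criterion, and the test
suite holds the tree-accelerated result equal to an O(n²) brute-force
oracle on every fixture. The paratope is the antibody side of the contact
relation (optionally intersected with CDR positions); the epitope is the
antigen side. Antigen residue ranges can be excluded from the relation
before projection — the intended use is dropping segments ordered only by
crystal packing (flexible coils) whose contacts are artifactual; both
readings (with and without the exclusion) remain available because
published interface counts do not always state which was used.

## Buried surface area

Solvent-accessible surface area uses a Shrake–Rupley sampler: a Fibonacci
lattice of test points per atom at the probe-expanded radius (probe
**1.4 Å**), occlusion against neighbouring expanded spheres, element-keyed
vdW radii in the Chothia/NACCESS convention (C 1.70, N 1.55, O 1.52,
S 1.80 Å; shipped as `data/sasa_radii.json`). The reporting default is
**960 points/atom**; machine-learning features use coarser sampling (120)
where only relative magnitudes matter. An isolated sphere reproduces
4π(r+p)² to well under 1 %, and doubling the point count moves it by <1 %.

Interface burial is reported under **both** common conventions: total
ΔSASA = SASA(A) + SASA(B) − SASA(AB), and ΔSASA/2. Per-side burials sum to
the total exactly (same sampling), which the tests assert. When comparing
against a published buried-surface figure, the convention that matches is
recorded rather than assumed.

## Shape complementarity

The S<sub>c</sub> statistic follows the Lawrence–Colman construction
adapted to dot surfaces on atoms: each side's solvent-exposed dots (placed
on the vdW sphere; accessibility judged at the expanded radius) are
restricted to the interfacial band — dots whose distance to the partner's
dot surface lies within **1.0 Å** of the surfaces' closest approach and
within **3.5 Å** absolutely — and the peripheral **20 %** of the band
(farthest from the partner) is trimmed. Each remaining dot contributes the
dot product of its outward normal with the reversed normal of the nearest
partner dot, damped by exp(−w·d²) with **w = 0.5 Å⁻²**; S<sub>c</sub> is
the mean of the two per-side medians. Normals are smoothed over
neighbouring dots within 1.5 Å to approximate the smooth molecular surface
on a discrete lattice. The adaptive band (rather than a fixed buried-dot
criterion) keeps the statistic defined for separated surfaces, which is
what makes the monotonicity-under-separation check computable. On the
ideally complementary knob-in-socket fixture the statistic exceeds 0.9 and
decreases strictly as a gap is inserted.

## Antibody numbering and germline analysis

Numbering is **alignment transfer**: the query V region is globally aligned
(BLOSUM62, gap open −11 / extend −1, free end gaps) to the best-matching
reference germline whose FASTA header carries explicit scheme numbers
(`>NAME|chain=H|imgt=1,2,...`), and numbers transfer across aligned
columns; query insertions take letters A, B, … on the preceding number, and
residues beyond the reference (CDR3 tail, FR4) continue sequentially. This
is a deliberate simplification of profile-HMM numbering: it is exact in the
near-germline regime that template-based engineering operates in, and
degrades gracefully (a <50 % identity match is rejected with a
wrong-chain-type hint; coverage short of IMGT position 104 — the end of
FR3 — is rejected as an incomplete V region). CDR boundaries are fixed at
IMGT 27–38 / 56–65 / 105–117.

Germline assignment returns the highest-identity gene (ties to the
alphabetically first name), with identity computed **over the germline
span only** — the query's CDR3/J tail is excluded, and gaps count as
mismatches. Per-position flags are then germline / mutated / uncovered;
positions beyond V-gene coverage are *uncovered*, never germline, so
germline-usage counts are conservative. Germline reference sequences are
user-supplied (licensing); the repository ships only synthetic stand-in
germlines for tests.

Cross-complex paratope conservation matches positions by (chain type,
scheme number, insertion letter). "Identical side chains" is a
sequence-level statement at matched positions (residue type equality, not
rotamer comparison), and the germline subset uses the first antibody's
flags. The nesting germline ⊆ identical ⊆ shared ⊆ paratope is enforced
structurally.

## Focused libraries

A library is a template Fv plus per-position allowed-residue sets and
insertion options. Counting is at the **protein level** (selection
campaigns report protein variants; DNA degeneracy is not the unit): an
optional insertion with k candidates contributes k+1 states, a varied
position contributes |allowed|, a position collapsed to the template
contributes 1. The closed-form product is verified against full
enumeration with distinct counting in both the tests and the acceptance
script; enumeration has a configurable ceiling (default 10⁶) above which
seeded uniform sampling is the supported mode. Degenerate codons translate
through the standard genetic code; stops are flagged and excluded from the
protein-level amino-acid set. Identity statistics treat a present insertion
as one non-match column (identity = matches / aligned length); minimum and
maximum are closed-form and the mean is the exact expectation over uniform
variants, all verified against enumeration on small specs. The shipped
first-generation example spec encodes the design's count structure — 16
two-state CDR positions plus one optional single-residue insertion in H3,
2¹⁶ × 2 = 131,072 variants on a ~230-residue Fv, minimum identity 92.6 % —
with illustrative residue choices that a user would replace with their own
design.

## Docking-pose classification

The docking engine itself is out of scope; poses are rigid-body placements
(unit quaternion + translation) supplied by the caller or by the decoy
generator. Near-native decoys perturb the native placement (defaults: up to
5° rotation about the antibody centroid, 1 Å translation); far decoys place
a randomly oriented antibody on a sphere around the antigen with 1–10 Å
clearance and clash rejection (no heavy-atom pair < 2.0 Å, bounded
retries). Pose quality is **fnat** — the fraction of native residue
contacts (5 Å) preserved — and class labels are native-like (fnat ≥ 0.5) /
decoy (≤ 0.1) / ambiguous (excluded from training); thresholds are
configurable and recorded in model metadata.

Features per pose: interface size (residue count, buried area), interface
amino-acid composition (20 fractions per side), specific-interaction counts
(hydrogen-bond surrogate: N/O heavy-atom pairs ≤ 3.5 Å — deposited models
lack hydrogens, so no angular term; opposite-charge side-chain pairs
≤ 4.0 Å), and the pose's standing in its docking run's score distribution
(rank, z-score, percentile; neutral constants 0 / 0.0 / 0.5 when no engine
scores exist). The classifier is a random forest (default 500 trees,
unlimited depth, √p features per split, explicit seed; tests use 100–150
trees for speed) evaluated by **grouped** cross-validation — no source
complex contributes poses to more than one fold — reporting per-fold and
pooled AUC. Panel screening scores each candidate antibody's poses,
retains the best, sorts descending (ties by antibody id) and reports each
hit's implied epitope (antigen residues within 5 Å of the best pose).

## Pairwise interaction scoring

Corpus curation keeps complexes with resolution strictly < 3.0 Å, protein
antigens, and no single-chain antibodies, then collapses redundancy:
entries are redundant when antigen sequence identity > 95 % **and**
antigen-binding-region identity > 85 %; redundancy is closed transitively
(union–find) and each group keeps its best-resolution entry (ties to the
lexicographically first id), so the survivor set is independent of input
order. Antigen-binding regions are approximated as IMGT CDRs ± 2 flanking
positions where structural ABR definitions are unavailable offline.

Each (antibody position, antigen residue) pair is an example: one-hot
residue types (20+20), antibody region one-hot (FR/CDR1/2/3), antigen
relative solvent exposure, antigen ±2 sequence context, and
physico-chemical complementarity terms (charge product, hydrophobicity
product, volume sum). The feature schema is versioned so persisted models
fail loudly on mismatch. Negative (non-contact) pairs are subsampled per
entry at a stated ratio with a seed. Heavy and light chains train
separately; cross-validation is fourfold and grouped by entry. Query
scoring evaluates every antibody position against every **exposed** antigen
residue (relative exposure ≥ 0.05, from the SASA machinery against a
200 Å² full-exposure scale); the argmax and all tie-breaks are
deterministic (lowest row index, then column). An epitope patch is the
antigen residues of the top-k pairs, expanded with spatial neighbours
(centroid distance ≤ 8 Å by default) drawn from the next tier of
top-scoring columns, and reported with a mean supporting score and a
surface-contiguity flag.

The published performance of retrained pair classifiers depends on the
specific structure-database snapshot used for training and is therefore
not reproducible offline; the pipeline exposes the corpus builder so a user
with downloaded structures can re-train, and all shipped tests use
synthetic corpora with planted signal.

## Aggregation propensity

For every atom, SAP sums — over side-chain atoms within **5.0 Å** — each
atom's SASA divided by the fully exposed side-chain SASA of its residue
type, weighted by the residue's hydrophobicity on the Black–Mould scale
re-centred at glycine (polar residues contribute negatively). The
per-residue score is the maximum over the residue's atoms (hotspots are
local maxima); the mean is reported alongside. The full-exposure reference
is a literature Gly-X-Gly table shipped as data
(`data/max_sidechain_sasa.json`) rather than recomputed from generated
tripeptide coordinates — the table is the quantity of interest and shipping
it keeps the computation reproducible byte-for-byte. Hotspot ranking
(descending score, ties by residue id; optionally surface-only, i.e.
strictly positive scores) attaches polarity-increasing substitution
suggestions from a fixed aromatic/hydrophobic → polar table (Y→N/S,
W→S/N/F, F→S/Y, …). This module is a documented open reconstruction of the
SAP family of developability predictors, not a reimplementation of any
vendor tool; vendor-reported hotspot identities are qualitative anchors
only.

Numerical note: SASA from a fixed point lattice is exactly translation
invariant but only approximately rotation invariant; SAP scores move by
well under 0.05 (dimensionless) under rigid rotation at the default
sampling, and the tests pin that bound rather than an unattainable exact
one.

## Synthetic fixtures

Generators are pure functions of (seed, spec) and emit machine-readable
ground truth beside the data. The planted-interface ladder places residue
pairs at ≤ ~4.5 Å and all other cross-chain pairs at ≥ 7 Å, so the 5 Å
contact oracle is exact and robust to floating-point jitter; behaviour at
exactly 5.0 Å is tested separately with hand-placed atoms. The
knob-in-socket shells provide an ideally complementary interface for the
S<sub>c</sub> checks (the socket lattice is deliberately coarser, 2 Å,
because a concave face packed tighter than the probe radius loses dot
coverage). The pair-corpus generator plants a residue-type-pair contact
signal: contact probability is a base rate (0.1) multiplied by the
enrichment factor (capped at 1) for signal-type pairs, and — so the signal
is learnable rather than drowned by background contacts — signal residue
types are made common (a position draws from the signal alphabet with
probability 0.7). Enrichment 1 restores a uniform contact rate regardless
of composition, which is what the null-band tests rely on. The synthetic
germlines carry full framework coverage (IMGT 1–104) with scheme gaps in
the CDRs and include deliberately divergent decoy genes.

These fixtures validate code contracts — exact planted counts, seeded
determinism, learnability of planted signal, null behaviour — not
biophysics: chains are lattices, not folds; corpora are random sequences,
not antibody repertoires. Passing tests therefore demonstrate that the
machinery measures what it claims on inputs with known truth, not that any
particular biological prediction is accurate.

## Known limitations

- Numbering is alignment-transfer, not profile-HMM: sequences far from any
  supplied germline (engineered frameworks, exotic species) are rejected
  rather than numbered.
- The hydrogen-bond surrogate is distance-only; no angular geometry, no
  water-mediated contacts.
- S<sub>c</sub> on dot surfaces approximates the molecular-surface
  statistic; absolute values depend mildly on the band/trim parameters,
  which are therefore configurable and documented rather than hidden.
- SAP is a single-structure surface calculation; it does not model
  conformational ensembles or charge-patch effects.
- No docking engine, no homology modelling, no structure refinement.
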
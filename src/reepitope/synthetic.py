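"""Deterministic generators for synthetic test inputs.

Every generator is a pure function of its seed and spec and emits its ground
truth in machine-readable form alongside the data.  The geometry of planted
interfaces keeps contact pairs well inside the 5 Å cutoff (≤ ~4.5 Å) and
non-contact pairs well outside (≥ 7 Å), so the contact oracle is robust to
floating-point jitter; boundary behaviour at exactly 5.0 Å is exercised by
hand-placed atoms in the tests instead.

These fixtures validate code contracts, not biophysics: chains are laid out
on regular lattices, not antibody folds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annotation import GermlineReference
from .interface import ContactSet
from .pairwise import CorpusEntry
from .sasa import fibonacci_sphere
from .structure import Atom, ComplexStructure, ResidueId

__all__ = [
    "ToyComplexSpec",
    "make_toy_complex",
    "make_pair_corpus",
    "make_redundant_twins",
    "make_toy_antibody",
    "germline_fasta_text",
    "make_nested_shells",
    "make_patch_ball",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclasses.dataclass(frozen=True)
class ToyComplexSpec:
    """Two-chain ladder complex with planted contact pairs.

    ``interface_residues`` lists 0-based residue indices k for which the pair
    (chain A residue k, chain B residue k) is a contact; all other cross-chain
    residue pairs are kept ≥ 7 Å apart.
    """

    n_residues_per_chain: tuple[int, int] = (8, 8)
    interface_residues: tuple[int, ...] = ()
    geometry: str = "two-sheet"
    seed: int = 0
    sequence_a: str | None = None
    sequence_b: str | None = None


def _residue_atoms(chain: str, index: int, resname: str, x: float, y: float, flip: bool) -> list[Atom]:
    """Three heavy atoms (N, CA, CB) of a minimal residue at lattice site x."""
    s = -1.0 if flip else 1.0
    coords = {
        "N": (x - 1.2, y, 0.0),
        "CA": (x, y, 0.0),
        "CB": (x, y + s * 1.5, 0.0),
    }
    return [
        Atom(
            chain_id=chain,
            residue_number=index + 1,
            insertion_code="",
            residue_name=resname,
            atom_name=name,
            element=name[0],
            coordinates=xyz,
        )
        for name, xyz in coords.items()
    ]


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexStructure, ContactSet]:
    """Build the ladder complex and its exact ground-truth 5 Å contact set."""
    n_a, n_b = spec.n_residues_per_chain
    planted = set(spec.interface_residues)
    if any(k >= min(n_a, n_b) or k < 0 for k in planted):
        raise ValueError("planted interface index outside both chains")
    rng = np.random.default_rng(spec.seed)
    seq_a = spec.sequence_a or "".join(rng.choice(list(_AA20), n_a))
    seq_b = spec.sequence_b or "".join(rng.choice(list(_AA20), n_b))
    if len(seq_a) != n_a or len(seq_b) != n_b:
        raise ValueError("sequence length must match n_residues_per_chain")

    atoms: list[Atom] = []
    for i in range(n_a):
        atoms += _residue_atoms("A", i, _ONE_TO_THREE[seq_a[i]], 10.0 * i, 0.0, flip=False)
    for j in range(n_b):
        y0 = 6.0 if j in planted else 13.0
        atoms += _residue_atoms("B", j, _ONE_TO_THREE[seq_b[j]], 10.0 * j, y0, flip=True)
    structure = ComplexStructure(atoms, title="toy ladder", source_id="TOY")
    truth = ContactSet(
        pairs=frozenset(
            (ResidueId("A", k + 1, ""), ResidueId("B", k + 1, "")) for k in planted
        ),
        cutoff=5.0,
    )
    return structure, truth


def make_pair_corpus(
    n_entries: int,
    signal: tuple[list[tuple[str, str]], float] = ([("R", "E"), ("K", "D")], 10.0),
    seed: int = 0,
    n_ab_positions: int = 12,
    n_antigen: int = 20,
    base_contact_prob: float = 0.1,
    signal_fraction: float = 0.7,
) -> list[CorpusEntry]:
    """Synthetic pair-training corpus with a planted residue-type-pair signal.

    Contacts are drawn per (antibody position, antigen residue) pair with
    probability ``base_contact_prob``, multiplied by the enrichment factor
    (capped at probability 1) when the residue-type pair is in the signal
    list.  So the signal is learnable rather than drowned in background
    contacts, the planted residue types are made common: with probability
    ``signal_fraction`` an antibody position draws its residue from the
    signal's antibody residues and an antigen position from the signal's
    antigen residues.  Enrichment 1 restores a uniform contact rate (no
    signal) regardless of composition.
    """
    pair_types, enrichment = signal
    if enrichment < 1:
        raise ValueError("enrichment factor must be ≥ 1")
    rng = np.random.default_rng(seed)
    pair_set = {(a, b) for a, b in pair_types}
    sig_ab = sorted({a for a, _ in pair_types})
    sig_ag = sorted({b for _, b in pair_types})
    entries: list[CorpusEntry] = []
    regions = ["FR", "CDR1", "CDR2", "CDR3"]

    def _draw(sig_pool: list[str]) -> str:
        if sig_pool and rng.random() < signal_fraction:
            return str(rng.choice(sig_pool))
        return str(rng.choice(list(_AA20)))

    for e in range(n_entries):
        ag_seq = "".join(_draw(sig_ag) for _ in range(n_antigen))
        ab_positions = []
        for i in range(n_ab_positions):
            chain = "H" if i < n_ab_positions // 2 else "L"
            region = regions[i % len(regions)]
            ab_positions.append((chain, region, _draw(sig_ab)))
        pairs = set()
        for i, (_, _, ab_res) in enumerate(ab_positions):
            for j, ag_res in enumerate(ag_seq):
                p = base_contact_prob
                if (ab_res, ag_res) in pair_set:
                    p = min(1.0, p * enrichment)
                if rng.random() < p:
                    pairs.add((i, j))
        abr = "".join(r for _, reg, r in ab_positions if reg.startswith("CDR"))
        entries.append(
            CorpusEntry(
                entry_id=f"SYN{e:03d}",
                resolution=float(rng.uniform(1.5, 2.9)),
                antigen_type="protein",
                is_single_chain_antibody=False,
                antigen_seq=ag_seq,
                abr_seqs=abr,
                ab_positions=ab_positions,
                labeled_pairs=pairs,
                antigen_exposure=list(rng.uniform(0.1, 1.0, n_antigen)),
            )
        )
    return entries


def make_redundant_twins(seed: int = 0) -> tuple[CorpusEntry, CorpusEntry]:
    """Two corpus entries on the redundant side of the curation thresholds:
    antigen identity 96% (> 95) and ABR identity 90% (> 85)."""
    rng = np.random.default_rng(seed)
    base = make_pair_corpus(1, seed=seed, n_antigen=100, n_ab_positions=40)[0]
    base.entry_id = "TWIN_A"
    base.resolution = 2.0
    ag = list(base.antigen_seq)
    for k in rng.choice(len(ag), 4, replace=False):  # 96/100 identical
        ag[k] = _AA20[(_AA20.index(ag[k]) + 1) % 20]
    abr = list(base.abr_seqs)
    for k in rng.choice(len(abr), max(1, len(abr) // 10), replace=False):
        abr[k] = _AA20[(_AA20.index(abr[k]) + 1) % 20]
    twin = dataclasses.replace(base) if dataclasses.is_dataclass(base) else base
    twin = CorpusEntry(
        entry_id="TWIN_B",
        resolution=2.5,
        antigen_type="protein",
        is_single_chain_antibody=False,
        antigen_seq="".join(ag),
        abr_seqs="".join(abr),
        ab_positions=list(base.ab_positions),
        labeled_pairs=set(base.labeled_pairs),
        antigen_exposure=list(base.antigen_exposure),
    )
    return base, twin


# IMGT scheme numbers carried by the synthetic germlines: full framework
# coverage 1..104 with scheme gaps inside CDR1/CDR2 (short loops).
_HEAVY_NUMBERS = (
    list(range(1, 27))          # FR1
    + [27, 28, 29, 30, 35, 36, 37, 38]   # CDR1 (8 residues)
    + list(range(39, 56))       # FR2
    + [56, 57, 58, 59, 62, 63, 64, 65]   # CDR2 (8 residues)
    + list(range(66, 105))      # FR3
)
_LIGHT_NUMBERS = (
    list(range(1, 27))
    + [27, 28, 29, 30, 31, 38]  # CDR1 (6 residues)
    + list(range(39, 56))
    + [56, 57, 65]              # CDR2 (3 residues)
    + list(range(66, 105))
)
_HEAVY_TAIL = "ARDRSYWGQGTLVTVSS"  # CDR3 + FR4, numbered sequentially after 104
_LIGHT_TAIL = "QQYDSSPWTFGQGTKVEIK"


def make_toy_antibody(
    seed: int = 0, n_mutations_from_germline: int = 0
) -> tuple[tuple[str, str], list[GermlineReference], list[tuple[str, int, str, str]]]:
    """Synthetic Fv + germline reference set + planted mutation ground truth.

    Returns ``((heavy_seq, light_seq), germline_refs, mutations)`` where each
    mutation is (chain 'H'/'L', scheme number, germline residue, observed
    residue).  Mutations are planted in the heavy chain's germline-covered
    span.  The reference set also contains decoy germlines of lower identity
    so best-match selection is exercised.
    """
    rng = np.random.default_rng(seed)

    def _germ(numbers) -> str:
        return "".join(rng.choice(list(_AA20), len(numbers)))

    heavy_germ = _germ(_HEAVY_NUMBERS)
    light_germ = _germ(_LIGHT_NUMBERS)
    refs = [
        GermlineReference("TOYHV1*01", "H", heavy_germ, tuple(_HEAVY_NUMBERS)),
        GermlineReference("TOYKV1*01", "K", light_germ, tuple(_LIGHT_NUMBERS)),
    ]
    # decoys: same numbering, ~30% of positions changed
    for name, chain, germ, nums in [
        ("TOYHV9*01", "H", heavy_germ, _HEAVY_NUMBERS),
        ("TOYKV9*01", "K", light_germ, _LIGHT_NUMBERS),
    ]:
        seq = list(germ)
        for k in rng.choice(len(seq), len(seq) // 3, replace=False):
            seq[k] = _AA20[(_AA20.index(seq[k]) + 7) % 20]
        refs.append(GermlineReference(name, chain, "".join(seq), tuple(nums)))

    heavy_q = list(heavy_germ)
    mutations: list[tuple[str, int, str, str]] = []
    if n_mutations_from_germline > len(heavy_q):
        raise ValueError("more mutations than heavy germline residues")
    for k in sorted(rng.choice(len(heavy_q), n_mutations_from_germline, replace=False)):
        old = heavy_q[k]
        new = _AA20[(_AA20.index(old) + 3) % 20]
        heavy_q[k] = new
        mutations.append(("H", _HEAVY_NUMBERS[k], old, new))
    heavy_seq = "".join(heavy_q) + _HEAVY_TAIL
    light_seq = light_germ + _LIGHT_TAIL
    return (heavy_seq, light_seq), refs, mutations


def germline_fasta_text(refs: list[GermlineReference]) -> str:
    """Serialize references in the numbered-header FASTA dialect."""
    lines = []
    for r in refs:
        nums = ",".join(str(n) for n in r.numbers)
        lines.append(f">{r.name}|chain={r.chain_type}|imgt={nums}")
        lines.append(r.sequence)
    return "\n".join(lines) + "\n"


def make_nested_shells(
    gap: float = 0.0,
    n_inner: int = 150,
    cap_cos: float = 0.5,
    outer_spacing: float = 2.0,
) -> ComplexStructure:
    """Ideally complementary toy interface: a spherical 'knob' (chain A) inside
    a concentric cap 'socket' (chain B) whose atoms sit at vdW contact
    distance + ``gap`` from the knob surface.  The socket lattice is coarser
    (``outer_spacing`` Å) so its concave inner face stays probe-accessible."""
    r_in = 4.0
    r_out = r_in + 3.4 + gap  # two carbon vdW radii apart at gap 0
    atoms: list[Atom] = [
        # centre atom plugs the shell cavity so the knob has no inner surface
        Atom("A", 1, "", "ALA", "CA", "C", (0.0, 0.0, 0.0))
    ]
    inner = fibonacci_sphere(n_inner) * r_in
    for i, xyz in enumerate(inner):
        atoms.append(
            Atom("A", i + 2, "", "ALA", "CB", "C", tuple(xyz))
        )
    n_outer = int(round(4.0 * np.pi * r_out**2 / outer_spacing**2))
    outer = fibonacci_sphere(n_outer) * r_out
    j = 0
    for xyz in outer:
        if xyz[2] / r_out >= cap_cos:  # polar cap only
            j += 1
            atoms.append(Atom("B", j, "", "ALA", "CB", "C", tuple(xyz)))
    return ComplexStructure(atoms, title=f"nested shells gap={gap}", source_id="SHELL")


def make_patch_ball(
    n_residues: int = 48, patch_size: int = 6, seed: int = 0
) -> tuple[ComplexStructure, set[ResidueId]]:
    """Ball of surface residues with a planted exposed hydrophobic patch.

    All residues are serine except a polar-cap patch of tryptophans; every
    side chain points outward and is fully exposed, and residues are spaced
    beyond the default 5 Å neighbourhood so each residue's score reflects its
    own side chain — the planted hydrophobics occupy the top ranks exactly.
    """
    dirs = fibonacci_sphere(n_residues)
    order = np.argsort(-dirs[:, 2])  # closest to +z first
    patch_idx = set(order[:patch_size].tolist())
    atoms: list[Atom] = []
    truth: set[ResidueId] = set()
    for i, u in enumerate(dirs):
        resname = "TRP" if i in patch_idx else "SER"
        ca = u * 16.0
        cb = u * 17.6
        rid = ResidueId("A", i + 1, "")
        if i in patch_idx:
            truth.add(rid)
        atoms.append(Atom("A", i + 1, "", resname, "CA", "C", tuple(ca)))
        atoms.append(Atom("A", i + 1, "", resname, "CB", "C", tuple(cb)))
    return ComplexStructure(atoms, title="patch ball", source_id="PATCH"), truth
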
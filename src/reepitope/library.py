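"""Focused mutation library representation, counting and enumeration.

A library is a template Fv plus per-position allowed-residue sets and
optional single-residue insertions.  Counting is at the protein level: an
optional insertion with k candidate residues contributes k+1 states (absent,
or present with any candidate), a varied position contributes the size of
its allowed set, and positions whose allowed set collapses to the template
residue alone contribute a factor of 1.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Iterator

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "PositionDiversity",
    "InsertionOption",
    "LibrarySpec",
    "library_size",
    "expand_degenerate_codon",
    "enumerate_library",
    "identity_stats",
    "load_library_spec",
]

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_degenerate_codon(codon: str) -> tuple[set[str], bool]:
    """Amino acids encoded by a degenerate IUPAC codon, plus a stop flag.

    >>> aas, stop = expand_degenerate_codon("NNS")
    >>> len(aas), stop
    (20, True)
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    for c in codon:
        if c not in IUPAC_NT:
            raise ValueError(f"invalid IUPAC nucleotide {c!r} in {codon!r}")
    table = standard_dna_table
    aas: set[str] = set()
    stop = False
    for triplet in itertools.product(*(IUPAC_NT[c] for c in codon)):
        cdn = "".join(triplet)
        if cdn in table.stop_codons:
            stop = True
        else:
            aas.add(table.forward_table[cdn])
    return aas, stop


@dataclasses.dataclass(frozen=True)
class PositionDiversity:
    """Allowed residues at one template position (chain, 1-based index)."""

    chain: str  # 'H' or 'L'
    position: int
    allowed_residues: frozenset[str]
    encoding: str | None = None  # degenerate codon, if the DNA design is known

    def __post_init__(self):
        if not self.allowed_residues:
            raise ValueError("allowed_residues must be non-empty")
        if self.encoding is not None:
            aas, _ = expand_degenerate_codon(self.encoding)
            if aas != set(self.allowed_residues):
                raise ValueError(
                    f"codon {self.encoding} encodes {sorted(aas)}, not "
                    f"{sorted(self.allowed_residues)}"
                )


@dataclasses.dataclass(frozen=True)
class InsertionOption:
    """A single-residue insertion slot after a template position."""

    chain: str
    after_position: int
    inserted_residues: frozenset[str]
    optional: bool = True

    @property
    def n_states(self) -> int:
        return len(self.inserted_residues) + (1 if self.optional else 0)


@dataclasses.dataclass
class LibrarySpec:
    name: str
    template: dict[str, str]  # chain -> sequence
    diversities: list[PositionDiversity]
    insertions: list[InsertionOption]

    def __post_init__(self):
        seen = set()
        for d in self.diversities:
            if (d.chain, d.position) in seen:
                raise ValueError(f"duplicate diversity at {d.chain}{d.position}")
            seen.add((d.chain, d.position))
            seq = self.template.get(d.chain)
            if seq is None or not (1 <= d.position <= len(seq)):
                raise ValueError(f"position {d.chain}{d.position} not in template")
        for ins in self.insertions:
            seq = self.template.get(ins.chain)
            if seq is None or not (0 <= ins.after_position <= len(seq)):
                raise ValueError(
                    f"insertion after {ins.chain}{ins.after_position} not in template"
                )

    @property
    def template_fv(self) -> str:
        return "".join(self.template[c] for c in sorted(self.template))


def _position_factor(spec: LibrarySpec, d: PositionDiversity) -> int:
    # a set containing only the template residue collapses to factor 1
    return len(d.allowed_residues)


def library_size(spec: LibrarySpec) -> int:
    """Exact count of distinct protein variants encoded by the spec."""
    size = 1
    for d in spec.diversities:
        size *= _position_factor(spec, d)
    for ins in spec.insertions:
        size *= ins.n_states
    return size


def enumerate_library(
    spec: LibrarySpec,
    mode: str = "full",
    n: int = 0,
    seed: int = 0,
    ceiling: int = 10**6,
) -> Iterator[str]:
    """Yield variant Fv sequences (chains concatenated in sorted chain order).

    ``full`` streams each distinct variant exactly once in a deterministic
    order; ``sample`` yields ``n`` uniform draws over distinct variants.
    """
    import numpy as np

    size = library_size(spec)
    slots: list[tuple[str, int, bool, list[str]]] = []
    # (chain, position/after_position, is_insertion, states)
    for d in spec.diversities:
        slots.append((d.chain, d.position, False, sorted(d.allowed_residues)))
    for ins in spec.insertions:
        states = sorted(ins.inserted_residues)
        if ins.optional:
            states = [""] + states
        slots.append((ins.chain, ins.after_position, True, states))

    def _build(choice: tuple[str, ...]) -> str:
        chains = {c: list(s) for c, s in spec.template.items()}
        inserts: dict[str, list[tuple[int, str]]] = {c: [] for c in chains}
        for (chain, pos, is_ins, _), picked in zip(slots, choice):
            if is_ins:
                if picked:
                    inserts[chain].append((pos, picked))
            else:
                chains[chain][pos - 1] = picked
        out_parts = []
        for c in sorted(chains):
            seq = chains[c]
            for pos, res in sorted(inserts[c], reverse=True):
                seq = seq[:pos] + [res] + seq[pos:]
            out_parts.append("".join(seq))
        return "".join(out_parts)

    if mode == "full":
        if size > ceiling:
            raise ValueError(
                f"library size {size} exceeds enumeration ceiling {ceiling}; "
                "use mode='sample'"
            )
        for choice in itertools.product(*(s[3] for s in slots)):
            yield _build(choice)
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        state_lists = [s[3] for s in slots]
        for _ in range(n):
            choice = tuple(sl[rng.integers(len(sl))] for sl in state_lists)
            yield _build(choice)
    else:
        raise ValueError(f"unknown mode {mode!r}")


def identity_stats(spec: LibrarySpec) -> tuple[float, float, float]:
    """(min, max, mean) percent identity of library variants to the template.

    Identity = 100 × matches / aligned length; an insertion present in a
    variant aligns against a gap (one non-match column).  Min and max are
    closed-form; the mean is the exact expectation under uniform choice of
    variant, computed over insertion-presence combinations.
    """
    L = sum(len(s) for s in spec.template.values())
    # positions that can actually change
    changeable = []
    p_mismatch = []
    for d in spec.diversities:
        tmpl_res = spec.template[d.chain][d.position - 1]
        others = set(d.allowed_residues) - {tmpl_res}
        if others:
            changeable.append(d)
            p_mismatch.append(len(others) / len(d.allowed_residues))
    k = len(changeable)
    mandatory_ins = [i for i in spec.insertions if not i.optional]
    optional_ins = [i for i in spec.insertions if i.optional]

    min_ident = 100.0 * (L - k) / (L + len(spec.insertions))
    max_ident = 100.0 * (
        L - sum(1 for d in spec.diversities
                if spec.template[d.chain][d.position - 1] not in d.allowed_residues)
    ) / (L + len(mandatory_ins))

    # exact mean: expectation of matches is independent of insertion state;
    # aligned length varies only with how many optional insertions are present
    exp_matches = L - sum(p_mismatch)
    total = 0.0
    weight_total = 0.0
    for present in itertools.product([False, True], repeat=len(optional_ins)):
        w = 1.0
        n_ins = len(mandatory_ins)
        for ins, on in zip(optional_ins, present):
            w *= len(ins.inserted_residues) if on else 1
            n_ins += int(on)
        total += w * exp_matches / (L + n_ins)
        weight_total += w
    if not optional_ins:
        total, weight_total = exp_matches / (L + len(mandatory_ins)), 1.0
    mean_ident = 100.0 * total / weight_total
    return min_ident, max_ident, mean_ident


def load_library_spec(path: str | Path) -> LibrarySpec:
    """Read a LibrarySpec from its JSON document form.

    Schema::

        {"name": ..., "template": {"H": seq, "L": seq},
         "diversities": [{"chain": "H", "position": 110, "allowed": "WY",
                          "codon": "NNS"?}, ...],
         "insertions": [{"chain": "H", "after_position": 109,
                         "residues": "G", "optional": true}, ...]}
    """
    doc = json.loads(Path(path).read_text())
    diversities = [
        PositionDiversity(
            chain=d["chain"],
            position=int(d["position"]),
            allowed_residues=frozenset(d["allowed"]),
            encoding=d.get("codon"),
        )
        for d in doc.get("diversities", [])
    ]
    insertions = [
        InsertionOption(
            chain=i["chain"],
            after_position=int(i["after_position"]),
            inserted_residues=frozenset(i["residues"]),
            optional=bool(i.get("optional", True)),
        )
        for i in doc.get("insertions", [])
    ]
    return LibrarySpec(
        name=doc.get("name", Path(path).stem),
        template={k: v.upper() for k, v in doc["template"].items()},
        diversities=diversities,
        insertions=insertions,
    )
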
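"""Macromolecular structure model and I/O.

Structures are reduced at load time to the protein heavy-atom content that
interface geometry operates on: waters, ions, ligands and hydrogens are
dropped, and alternate conformations are resolved to a single atom per
(residue, atom name) by occupancy.  Author residue numbering with insertion
codes is the canonical residue coordinate system throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueId",
    "ComplexStructure",
    "load_structure",
    "select_chains",
    "chain_sequence",
    "write_pdb",
]

# Fallbacks for residues gemmi does not tabulate; everything else resolves
# through gemmi's chemical component table.
_EXTRA_THREE_TO_ONE = {"MSE": "M", "SEC": "U", "PYL": "O"}


class ResidueId(NamedTuple):
    """Author-numbering residue coordinate: chain, number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.residue_number}{self.insertion_code}"


@dataclasses.dataclass(frozen=True)
class Atom:
    """A heavy atom with author-numbered residue identity."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coordinates: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_number, self.insertion_code)


class ComplexStructure:
    """An ordered collection of heavy atoms from one or more protein chains.

    Parameters
    ----------
    atoms:
        Atoms in file order.
    title, source_id:
        Free-text provenance (e.g. a PDB accession).
    """

    def __init__(self, atoms: Sequence[Atom], title: str = "", source_id: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        self.source_id = source_id
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (
            f"ComplexStructure({self.source_id or self.title!r}, "
            f"{len(self.atoms)} atoms, chains {sorted(self.chain_ids())})"
        )

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 array of atom coordinates in Å (cached)."""
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array(
                [a.coordinates for a in self.atoms], dtype=float
            ).reshape(len(self.atoms), 3)
        return self._coords

    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def residue_ids(self, chain_id: str | None = None) -> list[ResidueId]:
        """Distinct residue ids in atom order, optionally for one chain."""
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_name(self, rid: ResidueId) -> str:
        for a in self.atoms:
            if a.residue_id == rid:
                return a.residue_name
        raise KeyError(f"residue {rid} not in structure")

    def atom_indices_by_residue(self) -> dict[ResidueId, list[int]]:
        out: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Return a copy with coordinates x -> R x + t (rigid transform)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_xyz = self.coords @ rotation.T + translation
        atoms = [
            dataclasses.replace(a, coordinates=tuple(new_xyz[i]))
            for i, a in enumerate(self.atoms)
        ]
        return ComplexStructure(atoms, title=self.title, source_id=self.source_id)


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None and info.is_amino_acid():
        return True
    return residue_name in _EXTRA_THREE_TO_ONE


def three_to_one(residue_name: str) -> str:
    """3-letter residue code -> 1-letter; non-standard amino acids -> 'X'."""
    name = residue_name.upper()
    if name in _EXTRA_THREE_TO_ONE:
        return _EXTRA_THREE_TO_ONE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def load_structure(path: str | Path, format: str | None = None) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Waters, ions, ligands and hydrogens are dropped; only amino-acid polymer
    residues are kept.  For alternate locations the highest-occupancy altloc
    wins (ties: altloc 'A', then lexicographic).  Author numbering and
    insertion codes are preserved.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"`` or ``"mmcif"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}: expected 'pdb' or 'mmcif'")
    try:
        if format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc

    st.setup_entities()
    model = st[0]

    # candidate atoms per (residue, atom name); altloc resolved afterwards
    candidates: dict[tuple[ResidueId, str], list[Atom]] = {}
    order: list[tuple[ResidueId, str]] = []
    for chain in model:
        for res in chain:
            if res.name == "HOH" or not _is_amino_acid(res.name):
                continue
            rid = ResidueId(chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atom = Atom(
                    chain_id=rid.chain_id,
                    residue_number=rid.residue_number,
                    insertion_code=rid.insertion_code,
                    residue_name=res.name,
                    atom_name=at.name,
                    element=at.element.name,
                    coordinates=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=float(at.occ),
                    altloc=(at.altloc or "").strip(),
                )
                key = (rid, at.name)
                if key not in candidates:
                    candidates[key] = []
                    order.append(key)
                candidates[key].append(atom)

    atoms: list[Atom] = []
    for key in order:
        group = candidates[key]
        if len(group) == 1:
            atoms.append(group[0])
        else:
            # highest occupancy; ties -> altloc 'A', then lexicographic
            atoms.append(
                min(group, key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc))
            )
    return ComplexStructure(atoms, title=st.name or "", source_id=path.stem.upper())


def select_chains(structure: ComplexStructure, chain_ids: Iterable[str]) -> ComplexStructure:
    """Subset a structure to the named chains, preserving atom order."""
    wanted = set(chain_ids)
    available = structure.chain_ids()
    missing = wanted - available
    if missing:
        raise KeyError(
            f"chains {sorted(missing)} not in structure; available: {sorted(available)}"
        )
    atoms = [a for a in structure.atoms if a.chain_id in wanted]
    return ComplexStructure(atoms, title=structure.title, source_id=structure.source_id)


def chain_sequence(structure: ComplexStructure, chain_id: str) -> str:
    """One-letter amino-acid sequence of a chain in author-numbering order."""
    if chain_id not in structure.chain_ids():
        raise KeyError(
            f"chain {chain_id!r} not in structure; available: "
            f"{sorted(structure.chain_ids())}"
        )
    return "".join(
        three_to_one(structure.residue_name(rid))
        for rid in structure.residue_ids(chain_id)
    )


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records + TER/END) for fixtures."""
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        x, y, z = a.coordinates
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:<3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
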
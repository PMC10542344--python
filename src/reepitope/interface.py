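"""Antibody–antigen interface analysis.

Contacts, paratope/epitope extraction, buried surface area, shape
complementarity, and cross-complex paratope conservation.  A paratope is
the set of antibody residues with any heavy atom within the cutoff
(default 5.0 Å, inclusive) of the antigen; the epitope is the antigen side
of the same relation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotation import AnnotatedAntibody
from .sasa import DEFAULT_PROBE, accessible_points, atom_radii, shrake_rupley
from .structure import ComplexStructure, ResidueId, select_chains

__all__ = [
    "ContactSet",
    "InterfaceAreaReport",
    "ConservationReport",
    "contact_residues",
    "paratope_epitope",
    "interface_area",
    "shape_complementarity",
    "compare_paratopes",
    "map_residues_to_positions",
]

PosKey = tuple[str, int, str]  # (chain_type, scheme number, insertion letter)


@dataclasses.dataclass(frozen=True)
class ContactSet:
    pairs: frozenset[tuple[ResidueId, ResidueId]]
    cutoff: float

    @property
    def side_a_residues(self) -> set[ResidueId]:
        return {a for a, _ in self.pairs}

    @property
    def side_b_residues(self) -> set[ResidueId]:
        return {b for _, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclasses.dataclass(frozen=True)
class InterfaceAreaReport:
    """ΔSASA bookkeeping for one interface.

    ``delta_sasa`` is the total area buried on complexation
    (SASA_A + SASA_B − SASA_complex); ``delta_sasa / 2`` is the other
    common reporting convention (per-side average).  Both are exposed so a
    comparison against literature values can state which convention matched.
    """

    sasa_a: float
    sasa_b: float
    sasa_complex: float
    buried_a: float
    buried_b: float

    @property
    def delta_sasa(self) -> float:
        return self.sasa_a + self.sasa_b - self.sasa_complex

    @property
    def delta_sasa_half(self) -> float:
        return self.delta_sasa / 2.0


@dataclasses.dataclass(frozen=True)
class ConservationReport:
    """Paratope conservation between two complexes, on scheme-numbered positions."""

    positions_a: frozenset[PosKey]
    shared_positions: frozenset[PosKey]
    identical_sidechains: frozenset[PosKey]
    germline_identical: frozenset[PosKey]

    def __post_init__(self):
        if not (
            self.germline_identical
            <= self.identical_sidechains
            <= self.shared_positions
            <= self.positions_a
        ):
            raise ValueError("conservation sets must be nested")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "positions_a": len(self.positions_a),
            "shared": len(self.shared_positions),
            "identical": len(self.identical_sidechains),
            "germline_identical": len(self.germline_identical),
        }


def contact_residues(
    structure: ComplexStructure,
    side_a_chains: Iterable[str],
    side_b_chains: Iterable[str],
    cutoff: float = 5.0,
) -> ContactSet:
    """Residue pairs with any heavy-atom distance ≤ cutoff across the two sides."""
    side_a = set(side_a_chains)
    side_b = set(side_b_chains)
    if side_a & side_b:
        raise ValueError(f"chain sets overlap: {sorted(side_a & side_b)}")
    idx_a = [i for i, a in enumerate(structure.atoms) if a.chain_id in side_a]
    idx_b = [i for i, a in enumerate(structure.atoms) if a.chain_id in side_b]
    missing = (side_a | side_b) - structure.chain_ids()
    if missing:
        raise KeyError(
            f"chains {sorted(missing)} not in structure; available: "
            f"{sorted(structure.chain_ids())}"
        )
    pairs: set[tuple[ResidueId, ResidueId]] = set()
    if idx_a and idx_b:
        coords = structure.coords
        tree_b = cKDTree(coords[idx_b])
        hits = cKDTree(coords[idx_a]).query_ball_tree(tree_b, cutoff)
        for ia, blist in zip(idx_a, hits):
            rid_a = structure.atoms[ia].residue_id
            for jb in blist:
                pairs.add((rid_a, structure.atoms[idx_b[jb]].residue_id))
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def _in_range(rid: ResidueId, ranges: Sequence[tuple[str, int, int]]) -> bool:
    return any(
        rid.chain_id == ch and lo <= rid.residue_number <= hi for ch, lo, hi in ranges
    )


def map_residues_to_positions(
    annotated: AnnotatedAntibody,
    structure: ComplexStructure,
    chain_map: Mapping[str, str],
    residues: Iterable[ResidueId],
) -> set[PosKey]:
    """Map structure residues of antibody chains to scheme-numbered positions.

    ``chain_map`` sends structure chain ids to ``'H'`` / ``'L'``.  The i-th
    residue of a chain (author order) corresponds to the i-th numbered
    position of that chain's annotation.
    """
    lookup: dict[ResidueId, PosKey] = {}
    for struct_chain, ab_chain in chain_map.items():
        positions = annotated.heavy if ab_chain == "H" else annotated.light
        rids = structure.residue_ids(struct_chain)
        if len(rids) < len(positions):
            raise ValueError(
                f"chain {struct_chain} has {len(rids)} residues but the "
                f"annotation numbers {len(positions)}"
            )
        for rid, pos in zip(rids, positions):
            lookup[rid] = (ab_chain, pos.scheme_number, pos.insertion_letter)
    out = set()
    for rid in residues:
        if rid in lookup:
            out.add(lookup[rid])
    return out


def paratope_epitope(
    structure: ComplexStructure,
    antibody_chains: Iterable[str],
    antigen_chains: Iterable[str],
    cutoff: float = 5.0,
    restrict_to_cdr: bool = False,
    annotated: AnnotatedAntibody | None = None,
    chain_map: Mapping[str, str] | None = None,
    exclude_antigen_ranges: Sequence[tuple[str, int, int]] = (),
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Antibody (paratope) and antigen (epitope) residues at the interface.

    With ``restrict_to_cdr`` the paratope is intersected with CDR positions of
    ``annotated`` (``chain_map``: structure chain id -> 'H'/'L').
    ``exclude_antigen_ranges`` drops stated antigen segments — e.g. flexible
    coil residues ordered only through crystal packing — from both sides of
    the contact relation before projection.
    """
    if restrict_to_cdr and annotated is None:
        raise ValueError("restrict_to_cdr requires an annotated antibody")
    contacts = contact_residues(structure, antibody_chains, antigen_chains, cutoff)
    pairs = [
        (a, b) for a, b in contacts.pairs if not _in_range(b, exclude_antigen_ranges)
    ]
    paratope = {a for a, _ in pairs}
    epitope = {b for _, b in pairs}
    if restrict_to_cdr:
        if chain_map is None:
            chain_map = {c: ("H" if c.upper().startswith("H") else "L") for c in antibody_chains}
        lookup = {}
        for struct_chain, ab_chain in chain_map.items():
            positions = annotated.heavy if ab_chain == "H" else annotated.light
            for rid, pos in zip(structure.residue_ids(struct_chain), positions):
                lookup[rid] = pos
        paratope = {
            rid
            for rid in paratope
            if rid in lookup and lookup[rid].region.startswith("CDR")
        }
    return paratope, epitope


def interface_area(
    structure: ComplexStructure,
    side_a_chains: Iterable[str],
    side_b_chains: Iterable[str],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = 960,
) -> InterfaceAreaReport:
    """Buried surface area of the interface by three SASA evaluations."""
    side_a = set(side_a_chains)
    side_b = set(side_b_chains)
    if side_a & side_b:
        raise ValueError(f"chain sets overlap: {sorted(side_a & side_b)}")
    st_a = select_chains(structure, side_a)
    st_b = select_chains(structure, side_b)
    if len(st_a) == 0 or len(st_b) == 0:
        raise ValueError("each side must contain at least one atom")
    rad_a = atom_radii([a.element for a in st_a.atoms])
    rad_b = atom_radii([a.element for a in st_b.atoms])
    sasa_a = shrake_rupley(st_a.coords, rad_a, probe_radius, n_points)
    sasa_b = shrake_rupley(st_b.coords, rad_b, probe_radius, n_points)
    coords_ab = np.vstack([st_a.coords, st_b.coords])
    rad_ab = np.concatenate([rad_a, rad_b])
    sasa_ab = shrake_rupley(coords_ab, rad_ab, probe_radius, n_points)
    buried_a = sasa_a.sum() - sasa_ab[: len(st_a)].sum()
    buried_b = sasa_b.sum() - sasa_ab[len(st_a):].sum()
    return InterfaceAreaReport(
        sasa_a=float(sasa_a.sum()),
        sasa_b=float(sasa_b.sum()),
        sasa_complex=float(sasa_ab.sum()),
        buried_a=float(buried_a),
        buried_b=float(buried_b),
    )


def shape_complementarity(
    structure: ComplexStructure,
    side_a_chains: Iterable[str],
    side_b_chains: Iterable[str],
    weight: float = 0.5,
    n_points: int = 240,
    probe_radius: float = DEFAULT_PROBE,
    interface_width: float = 3.5,
    band_width: float = 1.0,
    trim_fraction: float = 0.2,
    smoothing_radius: float = 1.5,
) -> float:
    """Shape complementarity statistic of an interface, in [-1, 1].

    Lawrence–Colman-style: each side's solvent-exposed dot surface is
    restricted to the interfacial band — dots whose distance to the partner's
    dot surface lies within ``band_width`` Å of the surfaces' closest
    approach (and within ``interface_width`` absolutely) — and the
    peripheral ``trim_fraction`` of that band, the dots farthest from the
    partner surface, is discarded.  For every remaining dot the statistic
    takes the dot product of its outward normal with the reversed normal of
    the nearest partner dot, damped by exp(-weight · d²) with ``weight`` in
    Å⁻²; the result is the mean of the two per-side medians.  Normals are
    averaged over neighbouring dots within ``smoothing_radius`` to
    approximate the smooth molecular surface on a discrete atomic dot
    lattice.
    """
    st_a = select_chains(structure, set(side_a_chains))
    st_b = select_chains(structure, set(side_b_chains))
    rad_a = atom_radii([a.element for a in st_a.atoms])
    rad_b = atom_radii([a.element for a in st_b.atoms])
    pts_a, nrm_a, _ = accessible_points(st_a.coords, rad_a, probe_radius, n_points)
    pts_b, nrm_b, _ = accessible_points(st_b.coords, rad_b, probe_radius, n_points)
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise ValueError("a side has no solvent-exposed surface")

    tree_a = cKDTree(pts_a)
    tree_b = cKDTree(pts_b)
    d_ab, _ = tree_b.query(pts_a)
    d_ba, _ = tree_a.query(pts_b)

    def _band(d):
        sel = d <= interface_width
        if not sel.any():
            return sel
        d0 = np.quantile(d[sel], 0.05)  # closest approach, robust to outliers
        sel &= d <= d0 + band_width
        if 0.0 < trim_fraction < 1.0:
            sel &= d <= np.quantile(d[sel], 1.0 - trim_fraction)
        return sel

    sel_a = _band(d_ab)
    sel_b = _band(d_ba)
    if not sel_a.any() or not sel_b.any():
        raise ValueError("empty interface: no facing surface within the interface band")

    def _smooth(pts, nrm):
        tree = cKDTree(pts)
        out = np.empty_like(nrm)
        for i, nbrs in enumerate(tree.query_ball_point(pts, smoothing_radius)):
            v = nrm[nbrs].sum(axis=0)
            norm = np.linalg.norm(v)
            out[i] = v / norm if norm > 0 else nrm[i]
        return out

    ipts_a, inrm_a = pts_a[sel_a], _smooth(pts_a[sel_a], nrm_a[sel_a])
    ipts_b, inrm_b = pts_b[sel_b], _smooth(pts_b[sel_b], nrm_b[sel_b])

    def _side_median(pts_x, nrm_x, pts_y, nrm_y):
        d, j = cKDTree(pts_y).query(pts_x)
        s = np.einsum("ij,ij->i", nrm_x, -nrm_y[j]) * np.exp(-weight * d**2)
        return float(np.median(s))

    return 0.5 * (
        _side_median(ipts_a, inrm_a, ipts_b, inrm_b)
        + _side_median(ipts_b, inrm_b, ipts_a, inrm_a)
    )


def compare_paratopes(
    annot_a: AnnotatedAntibody,
    paratope_a: set[PosKey],
    annot_b: AnnotatedAntibody,
    paratope_b: set[PosKey],
) -> ConservationReport:
    """Conservation of antibody A's paratope positions in antibody B's complex.

    Positions are matched by (chain type, scheme number, insertion letter);
    ``identical_sidechains`` additionally requires the same residue type and
    ``germline_identical`` requires A's germline flag at the position.
    """
    if annot_a.scheme != annot_b.scheme:
        raise ValueError(
            f"numbering schemes differ: {annot_a.scheme} vs {annot_b.scheme}"
        )

    def _res(annot: AnnotatedAntibody, key: PosKey) -> str | None:
        positions = annot.heavy if key[0] == "H" else annot.light
        for p in positions:
            if (p.scheme_number, p.insertion_letter) == (key[1], key[2]):
                return p.residue
        return None

    shared = {k for k in paratope_a if k in paratope_b}
    identical = {k for k in shared if _res(annot_a, k) == _res(annot_b, k)}
    germline = {k for k in identical if annot_a.germline_flags.get(k) is True}
    return ConservationReport(
        positions_a=frozenset(paratope_a),
        shared_positions=frozenset(shared),
        identical_sidechains=frozenset(identical),
        germline_identical=frozenset(germline),
    )
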
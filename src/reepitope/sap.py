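"""Spatial aggregation propensity (SAP) of protein surfaces.

For every atom, SAP sums — over all side-chain atoms within a spatial radius
(default 5 Å) — each atom's solvent exposure (its SASA divided by the fully
exposed side-chain SASA of its residue type) weighted by the residue's
hydrophobicity on a glycine-centred Black–Mould scale.  Exposed hydrophobic
patches score positive, polar surfaces negative, buried side chains zero.
The per-residue score is the maximum over the residue's atoms (hotspots are
local maxima); the mean is reported alongside.

This is an open reconstruction of the SAP family of developability
predictors; it flags candidate positions for polarity-increasing redesign.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .sasa import atom_radii, shrake_rupley
from .structure import ComplexStructure, ResidueId, three_to_one

__all__ = ["SapScore", "sap_scores", "rank_hotspots", "POLAR_SUBSTITUTIONS"]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

# aromatic / hydrophobic -> polar redesign suggestions
POLAR_SUBSTITUTIONS = {
    "Y": "NS",
    "W": "SNF",
    "F": "SY",
    "L": "STN",
    "I": "STN",
    "V": "ST",
    "M": "ST",
    "A": "S",
}


def _load_tables() -> tuple[dict[str, float], dict[str, float]]:
    hydro_doc = json.loads(
        resources.files("reepitope.data")
        .joinpath("hydrophobicity_black_mould.json")
        .read_text()
    )
    center = hydro_doc["scale"][hydro_doc["center_on"]]
    hydro = {aa: v - center for aa, v in hydro_doc["scale"].items()}
    ref_doc = json.loads(
        resources.files("reepitope.data").joinpath("max_sidechain_sasa.json").read_text()
    )
    return hydro, {k: float(v) for k, v in ref_doc["sasa"].items()}


_HYDRO, _REF_SASA = _load_tables()


@dataclasses.dataclass(frozen=True)
class SapScore:
    residue: ResidueId
    residue_name: str
    score: float  # max over the residue's atoms
    mean_score: float
    radius: float
    contributing_atoms: int


def sap_scores(
    structure: ComplexStructure,
    radius: float = 5.0,
    n_points: int = 480,
) -> list[SapScore]:
    """Per-residue SAP scores (one entry per residue, in structure order)."""
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords = structure.coords
    radii = atom_radii([a.element for a in structure.atoms])
    atom_sasa = shrake_rupley(coords, radii, n_points=n_points)

    aa1 = np.array([three_to_one(a.residue_name) for a in structure.atoms])
    is_side = np.array(
        [a.atom_name.upper() not in _BACKBONE for a in structure.atoms]
    )
    known = np.array([aa in _HYDRO for aa in aa1])
    unknown_res = {
        a.residue_name for a, k in zip(structure.atoms, known) if not k
    }
    if unknown_res:
        warnings.warn(f"unknown residue types skipped by SAP: {sorted(unknown_res)}")

    # per-atom contribution of side-chain atom j if it falls in a neighborhood
    contrib = np.zeros(len(coords))
    ok = is_side & known
    for j in np.flatnonzero(ok):
        ref = _REF_SASA[aa1[j]]
        contrib[j] = (atom_sasa[j] / ref) * _HYDRO[aa1[j]]

    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, radius)
    atom_sap = np.zeros(len(coords))
    atom_nc = np.zeros(len(coords), dtype=int)
    for i, nbrs in enumerate(neighborhoods):
        sel = [j for j in nbrs if ok[j]]
        atom_sap[i] = contrib[sel].sum() if sel else 0.0
        atom_nc[i] = len(sel)

    out: list[SapScore] = []
    for rid, idx in structure.atom_indices_by_residue().items():
        idx = np.array(idx)
        out.append(
            SapScore(
                residue=rid,
                residue_name=structure.atoms[idx[0]].residue_name,
                score=float(atom_sap[idx].max()),
                mean_score=float(atom_sap[idx].mean()),
                radius=radius,
                contributing_atoms=int(atom_nc[idx].max()),
            )
        )
    return out


def rank_hotspots(
    scores: list[SapScore],
    top_n: int = 10,
    surface_only: bool = True,
) -> list[dict]:
    """Highest-SAP positions with polarity-increasing substitution suggestions.

    Descending by score, ties by residue id; with ``surface_only`` only
    positions with strictly positive SAP (exposed hydrophobics) are eligible.
    """
    if not scores:
        raise ValueError("no SAP scores supplied")
    eligible = [s for s in scores if (not surface_only) or s.score > 0.0]
    eligible.sort(key=lambda s: (-s.score, s.residue))
    out = []
    for s in eligible[:top_n]:
        aa = three_to_one(s.residue_name)
        out.append(
            {
                "residue": s.residue,
                "residue_name": s.residue_name,
                "score": s.score,
                "suggested_substitutions": POLAR_SUBSTITUTIONS.get(aa, ""),
            }
        )
    return out
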
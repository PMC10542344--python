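"""End-to-end analyses over deposited antibody–antigen complexes.

The cross-complex conservation workflow reproduces the comparison between a
template antibody bound to its original antigen and a re-engineered clone
bound to the new antigen: CDR paratopes at 5 Å, positions shared between the
two complexes, identical side chains among them, germline side chains among
those, plus buried surface area and shape complementarity.

Structure files are supplied by the user (deposited coordinates are not
redistributed with the package); germline V-gene references likewise.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .annotation import (
    AnnotatedAntibody,
    assign_germline,
    germline_flag_positions,
    number_antibody,
    read_germline_fasta,
)
from .interface import (
    compare_paratopes,
    interface_area,
    map_residues_to_positions,
    paratope_epitope,
    shape_complementarity,
)
from .structure import ComplexStructure, chain_sequence, load_structure

__all__ = ["annotate_from_structure", "conservation_analysis"]


def annotate_from_structure(
    structure: ComplexStructure,
    heavy_chain: str,
    light_chain: str,
    germline_refs,
) -> AnnotatedAntibody:
    """Number an antibody from its structure chains and flag germline positions."""
    heavy = chain_sequence(structure, heavy_chain)
    light = chain_sequence(structure, light_chain)
    ann = number_antibody(heavy, light, reference_set=germline_refs)
    asn_h = assign_germline(heavy, germline_refs, chain_types={"H"})
    asn_l = assign_germline(light, germline_refs, chain_types={"K", "L"})
    return germline_flag_positions(ann, {"H": asn_h, "L": asn_l})


def conservation_analysis(
    complex_a_path: str | Path,
    complex_b_path: str | Path,
    germline_fasta: str | Path,
    a_antibody_chains: tuple[str, str] = ("H", "L"),
    b_antibody_chains: tuple[str, str] = ("H", "L"),
    a_antigen_chains: Sequence[str] | None = None,
    b_antigen_chains: Sequence[str] = ("G", "I"),
    cutoff: float = 5.0,
    exclude_antigen_ranges_b: Sequence[tuple[str, int, int]] = (),
) -> dict:
    """Cross-complex paratope conservation and interface metrics.

    ``complex_a`` is the template antibody with its original antigen;
    ``complex_b`` the engineered clone with the new antigen.  Antigen chains
    default to every chain that is not an antibody chain (complex A) and to
    the stated pair (complex B, whose crystal carries several copies).
    ``exclude_antigen_ranges_b`` drops antigen segments ordered only through
    crystal packing (e.g. a flexible coil) from complex B's contact relation.
    """
    refs = read_germline_fasta(germline_fasta)
    st_a = load_structure(complex_a_path)
    st_b = load_structure(complex_b_path)
    ab_a = set(a_antibody_chains)
    ab_b = set(b_antibody_chains)
    ag_a = set(a_antigen_chains) if a_antigen_chains else st_a.chain_ids() - ab_a
    ag_b = set(b_antigen_chains)

    ann_a = annotate_from_structure(st_a, a_antibody_chains[0], a_antibody_chains[1], refs)
    ann_b = annotate_from_structure(st_b, b_antibody_chains[0], b_antibody_chains[1], refs)
    chain_map_a = {a_antibody_chains[0]: "H", a_antibody_chains[1]: "L"}
    chain_map_b = {b_antibody_chains[0]: "H", b_antibody_chains[1]: "L"}

    para_a, _ = paratope_epitope(
        st_a, ab_a, ag_a, cutoff, restrict_to_cdr=True, annotated=ann_a,
        chain_map=chain_map_a,
    )
    para_b_all, _ = paratope_epitope(
        st_b, ab_b, ag_b, cutoff,
        exclude_antigen_ranges=exclude_antigen_ranges_b,
    )
    keys_a = map_residues_to_positions(ann_a, st_a, chain_map_a, para_a)
    keys_b = map_residues_to_positions(ann_b, st_b, chain_map_b, para_b_all)
    conservation = compare_paratopes(ann_a, keys_a, ann_b, keys_b)

    area_a = interface_area(st_a, ab_a, ag_a)
    sc_a = shape_complementarity(st_a, ab_a, ag_a)

    return {
        "annotation_a": ann_a,
        "annotation_b": ann_b,
        "paratope_a_cdr_positions": sorted(keys_a),
        "paratope_b_positions": sorted(keys_b),
        "n_paratope_a": len(keys_a),
        "n_paratope_b": len(keys_b),
        "conservation": conservation,
        "counts": conservation.counts,
        "interface_area_a": area_a,
        "shape_complementarity_a": sc_a,
        "germline_a": ann_a.assigned_vgenes,
    }
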
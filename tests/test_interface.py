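"""Contacts, buried surface area, shape complementarity, conservation."""

import numpy as np
import pytest

from reepitope.annotation import assign_germline, germline_flag_positions, number_antibody
from reepitope.interface import (
    ConservationReport,
    compare_paratopes,
    contact_residues,
    interface_area,
    map_residues_to_positions,
    paratope_epitope,
    shape_complementarity,
)
from reepitope.sasa import shrake_rupley
from reepitope.structure import Atom, ComplexStructure
from reepitope.synthetic import (
    ToyComplexSpec,
    make_nested_shells,
    make_toy_antibody,
    make_toy_complex,
)


def _bruteforce_contacts(st, side_a, side_b, cutoff):
    coords = st.coords
    pairs = set()
    for i, a in enumerate(st.atoms):
        if a.chain_id not in side_a:
            continue
        for j, b in enumerate(st.atoms):
            if b.chain_id not in side_b:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add((a.residue_id, b.residue_id))
    return pairs


@pytest.mark.parametrize("seed", range(5))
def test_grid_contacts_equal_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    planted = tuple(sorted(rng.choice(8, rng.integers(0, 6), replace=False).tolist()))
    st, truth = make_toy_complex(ToyComplexSpec(interface_residues=planted, seed=seed))
    cs = contact_residues(st, {"A"}, {"B"}, 5.0)
    assert set(cs.pairs) == _bruteforce_contacts(st, {"A"}, {"B"}, 5.0)
    assert set(cs.pairs) == set(truth.pairs)


def test_contacts_symmetric_and_monotone(toy_complex):
    st, _ = toy_complex
    ab = contact_residues(st, {"A"}, {"B"}, 5.0)
    ba = contact_residues(st, {"B"}, {"A"}, 5.0)
    assert {(b, a) for a, b in ab.pairs} == set(ba.pairs)
    narrow = contact_residues(st, {"A"}, {"B"}, 4.0)
    assert set(narrow.pairs) <= set(ab.pairs)


def test_contact_cutoff_is_inclusive():
    def atom(chain, x):
        return Atom(chain, 1, "", "GLY", "CA", "C", (x, 0.0, 0.0))

    at_cutoff = ComplexStructure([atom("A", 0.0), atom("B", 5.0)])
    beyond = ComplexStructure([atom("A", 0.0), atom("B", 5.001)])
    assert len(contact_residues(at_cutoff, {"A"}, {"B"}, 5.0)) == 1
    assert len(contact_residues(beyond, {"A"}, {"B"}, 5.0)) == 0


def test_distant_single_atoms_no_contact():
    a = Atom("A", 1, "", "GLY", "CA", "C", (0.0, 0.0, 0.0))
    b = Atom("B", 1, "", "GLY", "CA", "C", (6.0, 0.0, 0.0))
    st = ComplexStructure([a, b])
    assert len(contact_residues(st, {"A"}, {"B"}, 5.0)) == 0


def test_overlapping_sides_rejected(toy_complex):
    st, _ = toy_complex
    with pytest.raises(ValueError, match="overlap"):
        contact_residues(st, {"A"}, {"A", "B"})


def test_paratope_epitope_recovers_planted_sides(toy_complex):
    st, truth = toy_complex
    para, epi = paratope_epitope(st, {"B"}, {"A"})
    assert para == {b for _, b in truth.pairs}
    assert epi == {a for a, _ in truth.pairs}


def test_tiny_cutoff_gives_empty_paratope(toy_complex):
    st, _ = toy_complex
    para, epi = paratope_epitope(st, {"B"}, {"A"}, cutoff=0.1)
    assert para == set() and epi == set()


def test_antigen_range_exclusion_drops_pairs(toy_complex):
    st, truth = toy_complex
    excluded = sorted(truth.pairs)[0][0]  # one planted chain-A (antigen) residue
    para, epi = paratope_epitope(
        st, {"B"}, {"A"},
        exclude_antigen_ranges=[("A", excluded.residue_number, excluded.residue_number)],
    )
    assert excluded not in epi
    assert len(epi) == len(truth.pairs) - 1


def test_isolated_sphere_sasa_closed_form():
    for r in (1.52, 1.7, 1.8):
        area = shrake_rupley(np.zeros((1, 3)), np.array([r]), n_points=960)[0]
        exact = 4.0 * np.pi * (r + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01


def test_sasa_point_count_convergence():
    r = 1.7
    a1 = shrake_rupley(np.zeros((1, 3)), np.array([r]), n_points=480)[0]
    a2 = shrake_rupley(np.zeros((1, 3)), np.array([r]), n_points=960)[0]
    assert abs(a2 - a1) / a2 < 0.01


def test_interface_area_additivity_and_positive(toy_complex):
    st, _ = toy_complex
    rep = interface_area(st, {"A"}, {"B"}, n_points=240)
    assert rep.delta_sasa > 0
    assert rep.buried_a + rep.buried_b == pytest.approx(rep.delta_sasa, abs=1e-9)
    assert rep.delta_sasa_half == pytest.approx(rep.delta_sasa / 2)


def test_interface_area_zero_for_distant_chains():
    st, _ = make_toy_complex(ToyComplexSpec(interface_residues=(), seed=1))
    rep = interface_area(st, {"A"}, {"B"}, n_points=240)
    assert rep.delta_sasa == pytest.approx(0.0, abs=1.0)


def test_interface_area_empty_side_errors(toy_complex):
    st, _ = toy_complex
    with pytest.raises((ValueError, KeyError)):
        interface_area(st, {"A"}, {"Z"})


def test_shape_complementarity_nested_and_separated():
    nested = shape_complementarity(make_nested_shells(0.0), {"A"}, {"B"})
    separated = shape_complementarity(make_nested_shells(2.0), {"A"}, {"B"})
    assert nested > 0.9
    assert separated < nested


def test_shape_complementarity_empty_interface_errors():
    st, _ = make_toy_complex(ToyComplexSpec(interface_residues=(), seed=2))
    # chains 13 Å apart: nothing within the interface band
    with pytest.raises(ValueError, match="interface"):
        shape_complementarity(st, {"A"}, {"B"}, interface_width=3.5)


def _annotate(heavy, light, refs):
    ann = number_antibody(heavy, light, reference_set=refs)
    asn_h = assign_germline(heavy, refs, chain_types={"H"})
    asn_l = assign_germline(light, refs, chain_types={"K"})
    return germline_flag_positions(ann, {"H": asn_h, "L": asn_l})


def test_compare_paratopes_self_is_fully_conserved(toy_antibody_clean):
    (heavy, light), refs, _ = toy_antibody_clean
    ann = _annotate(heavy, light, refs)
    paratope = {p.key for p in ann.heavy[:6]}
    rep = compare_paratopes(ann, paratope, ann, paratope)
    assert rep.shared_positions == rep.positions_a
    assert rep.identical_sidechains == rep.positions_a


def test_compare_paratopes_planted_counts():
    """Two near-germline antibodies with engineered differences at scheme
    positions 28 (A mutated) and 29 (both mutated identically):
    4 paratope positions, 3 shared, 2 identical, 1 germline."""
    (_, light), refs, _ = make_toy_antibody(seed=1, n_mutations_from_germline=0)
    germ = refs[0].sequence
    numbers = list(refs[0].numbers)
    i28, i29 = numbers.index(28), numbers.index(29)

    def mutate(seq, idx):
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        new = alphabet[(alphabet.index(seq[idx]) + 5) % 20]
        return seq[:idx] + new + seq[idx + 1:]

    heavy_a = mutate(mutate(germ, i28), i29) + "ARDRSYWGQGTLVTVSS"
    heavy_b = mutate(germ, i29) + "ARDRSYWGQGTLVTVSS"
    ann_a = _annotate(heavy_a, light, refs)
    ann_b = _annotate(heavy_b, light, refs)
    paratope_a = {("H", n, "") for n in (27, 28, 29, 30)}
    paratope_b = {("H", n, "") for n in (27, 28, 29)}
    rep = compare_paratopes(ann_a, paratope_a, ann_b, paratope_b)
    assert rep.counts == {
        "positions_a": 4,
        "shared": 3,
        "identical": 2,
        "germline_identical": 1,
    }


def test_conservation_nesting_enforced():
    with pytest.raises(ValueError, match="nested"):
        ConservationReport(
            positions_a=frozenset({("H", 1, "")}),
            shared_positions=frozenset({("H", 2, "")}),
            identical_sidechains=frozenset(),
            germline_identical=frozenset(),
        )


def test_scheme_mismatch_rejected(toy_antibody_clean):
    (heavy, light), refs, _ = toy_antibody_clean
    ann = _annotate(heavy, light, refs)
    import copy

    other = copy.copy(ann)
    other.scheme = "kabat"
    with pytest.raises(ValueError, match="scheme"):
        compare_paratopes(ann, set(), other, set())


def test_map_residues_to_positions_aligns_order(toy_complex, toy_antibody_clean):
    (heavy, light), refs, _ = toy_antibody_clean
    ann = _annotate(heavy, light, refs)
    # toy structure chains are short; map the first ladder residues of chain B
    st, _ = make_toy_complex(
        ToyComplexSpec(n_residues_per_chain=(len(heavy), len(light)), seed=9)
    )
    keys = map_residues_to_positions(
        ann, st, {"A": "H"}, set(st.residue_ids("A")[:3])
    )
    assert keys == {p.key for p in ann.heavy[:3]}
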
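"""Corpus curation, pair featurization, cross-validation, epitope patches."""

import numpy as np
import pytest

from reepitope.annotation import number_antibody
from reepitope.pairwise import (
    CorpusEntry,
    build_pair_dataset,
    crossval_pair_classifier,
    curate_corpus,
    pair_feature_names,
    predict_epitope_patch,
    score_all_pairs,
    site_overlap,
)
from reepitope.structure import select_chains, three_to_one
from reepitope.synthetic import (
    ToyComplexSpec,
    make_pair_corpus,
    make_redundant_twins,
    make_toy_antibody,
    make_toy_complex,
)


def _entry(entry_id="E1", resolution=2.0, antigen_type="protein", single=False,
           antigen_seq="ACDEFGHIKL", abr="RRKK", pairs=None):
    return CorpusEntry(
        entry_id=entry_id,
        resolution=resolution,
        antigen_type=antigen_type,
        is_single_chain_antibody=single,
        antigen_seq=antigen_seq,
        abr_seqs=abr,
        ab_positions=[("H", "CDR1", "R"), ("H", "CDR3", "K"), ("L", "CDR1", "S"),
                      ("L", "CDR3", "Y"), ("H", "FR", "G")],
        labeled_pairs=pairs if pairs is not None else {(0, 3), (1, 4), (2, 5)},
    )


def test_resolution_cut_is_strict():
    kept = curate_corpus([_entry("A", resolution=3.2), _entry("B", resolution=2.9)])
    assert [e.entry_id for e in kept] == ["B"]
    assert curate_corpus([_entry("C", resolution=3.0)]) == []


def test_non_protein_and_single_chain_excluded():
    kept = curate_corpus(
        [
            _entry("A", antigen_type="peptide"),
            _entry("B", single=True),
            _entry("C"),
        ]
    )
    assert [e.entry_id for e in kept] == ["C"]


def test_redundant_twins_collapse_to_best_resolution():
    a, b = make_redundant_twins(0)
    kept = curate_corpus([a, b])
    assert [e.entry_id for e in kept] == ["TWIN_A"]  # 2.0 Å beats 2.5 Å


def test_curation_empty_idempotent_order_independent():
    assert curate_corpus([]) == []
    corpus = make_pair_corpus(4, seed=1) + list(make_redundant_twins(1))
    once = curate_corpus(corpus)
    assert curate_corpus(once) == once
    reversed_out = curate_corpus(corpus[::-1])
    assert [e.entry_id for e in reversed_out] == [e.entry_id for e in once]


def test_dataset_counts_at_ratio_one():
    ds = build_pair_dataset([_entry()], negative_subsample_ratio=1.0, seed=0)
    assert (ds["y"] == 1).sum() == 3
    assert (ds["y"] == 0).sum() == 3
    assert ds["X"].shape[1] == len(pair_feature_names())


def test_ratio_zero_gives_positives_only():
    ds = build_pair_dataset([_entry()], negative_subsample_ratio=0.0, seed=0)
    assert (ds["y"] == 0).sum() == 0 and (ds["y"] == 1).sum() == 3


def test_negative_sampling_seed_deterministic():
    d1 = build_pair_dataset([_entry()], 1.0, seed=5)
    d2 = build_pair_dataset([_entry()], 1.0, seed=5)
    assert np.array_equal(d1["X"], d2["X"])


def test_entry_without_contacts_is_skipped_with_warning():
    with pytest.warns(UserWarning, match="no contact"):
        ds = build_pair_dataset([_entry(), _entry("E2", pairs=set())], 1.0, seed=0)
    assert set(ds["groups"]) == {"E1"}


def test_grouped_folds_never_split_an_entry(pair_dataset):
    from sklearn.model_selection import GroupKFold

    X, y, groups = pair_dataset["X"], pair_dataset["y"], pair_dataset["groups"]
    for train, test in GroupKFold(n_splits=4).split(X, y, groups):
        assert set(groups[train]) & set(groups[test]) == set()


def test_planted_signal_crossval_auc_both_chains(pair_dataset):
    for chain in ("heavy", "light"):
        _, report = crossval_pair_classifier(
            pair_dataset, chain, folds=4, n_trees=150, seed=0
        )
        assert report["pooled_auc"] >= 0.85


def test_shuffled_labels_in_null_band(pair_dataset):
    shuffled = dict(pair_dataset)
    shuffled["y"] = np.random.default_rng(0).permutation(pair_dataset["y"])
    _, report = crossval_pair_classifier(shuffled, "heavy", folds=4, n_trees=150, seed=0)
    assert 0.35 <= report["pooled_auc"] <= 0.65


def test_no_signal_corpus_in_null_band():
    corpus = make_pair_corpus(10, signal=([("R", "E"), ("K", "D")], 1.0), seed=0)
    ds = build_pair_dataset(corpus, 1.0, seed=0)
    _, report = crossval_pair_classifier(ds, "heavy", folds=4, n_trees=150, seed=0)
    assert 0.35 <= report["pooled_auc"] <= 0.65


def test_fewer_entries_than_folds_rejected():
    ds = build_pair_dataset([_entry()], 1.0, seed=0)
    with pytest.raises(ValueError, match="folds|entries"):
        crossval_pair_classifier(ds, "heavy", folds=4)


@pytest.fixture(scope="module")
def trained_pair_model(pair_dataset):
    forest, _ = crossval_pair_classifier(pair_dataset, "heavy", folds=4, n_trees=100, seed=0)
    return forest


@pytest.fixture(scope="module")
def toy_antigen():
    st, _ = make_toy_complex(
        ToyComplexSpec(
            n_residues_per_chain=(10, 10),
            interface_residues=(),
            seed=0,
            sequence_a="AEDGSKEDLV",
            sequence_b="G" * 10,
        )
    )
    return select_chains(st, {"A"})


def test_score_matrix_shape_and_determinism(trained_pair_model, toy_antigen, toy_antibody_clean):
    (h, l), refs, _ = toy_antibody_clean
    ann = number_antibody(h, l, reference_set=refs)
    m1 = score_all_pairs(ann, toy_antigen, trained_pair_model)
    m2 = score_all_pairs(ann, toy_antigen, trained_pair_model)
    assert m1.scores.shape == (len(ann.heavy) + len(ann.light), len(m1.cols))
    assert np.array_equal(m1.scores, m2.scores)
    assert np.all((m1.scores >= 0) & (m1.scores <= 1))


def test_top1_pair_recovers_planted_type_across_seeds(toy_antigen):
    hits = 0
    for s in range(5):
        corpus = make_pair_corpus(8, seed=s)
        ds = build_pair_dataset(corpus, 1.0, seed=s)
        forest, _ = crossval_pair_classifier(ds, "heavy", folds=4, n_trees=100, seed=0)
        (h, l), refs, _ = make_toy_antibody(seed=s)
        ann = number_antibody(h, l, reference_set=refs)
        row, col, _ = score_all_pairs(ann, toy_antigen, forest).argmax
        pos = next(p for p in ann.heavy + ann.light if p.key == row)
        ag_res = three_to_one(toy_antigen.residue_name(col))
        if (pos.residue, ag_res) in {("R", "E"), ("K", "D")}:
            hits += 1
    assert hits >= 4  # ≥ 80% of seeded replicates


def test_epitope_patch_top1_is_argmax(trained_pair_model, toy_antigen, toy_antibody_clean):
    (h, l), refs, _ = toy_antibody_clean
    ann = number_antibody(h, l, reference_set=refs)
    m = score_all_pairs(ann, toy_antigen, trained_pair_model)
    patch = predict_epitope_patch(m, toy_antigen, top_k=1, neighbor_radius=0.1)
    assert m.argmax[1] in patch["residues"]
    assert len(patch["supporting_pairs"]) == 1


def test_patch_contiguity_flag_spacing():
    """Ladder residues are 10 Å apart: a multi-residue patch is contiguous at
    a 12 Å neighbour radius and non-contiguous at 8 Å."""
    from reepitope.pairwise import PairScoreMatrix

    st, _ = make_toy_complex(
        ToyComplexSpec(n_residues_per_chain=(6, 6), interface_residues=(), seed=0)
    )
    antigen = select_chains(st, {"A"})
    rids = antigen.residue_ids()
    scores = np.zeros((2, len(rids)))
    scores[0, 0] = scores[0, 1] = scores[0, 2] = 1.0  # adjacent ladder sites
    m = PairScoreMatrix(rows=[("H", 27, ""), ("H", 28, "")], cols=rids, scores=scores)
    wide = predict_epitope_patch(m, antigen, top_k=3, neighbor_radius=12.0)
    tight = predict_epitope_patch(m, antigen, top_k=3, neighbor_radius=8.0)
    assert wide["contiguous"] is True
    assert tight["contiguous"] is False


def test_uniform_scores_tie_break_row_major():
    from reepitope.pairwise import PairScoreMatrix

    st, _ = make_toy_complex(
        ToyComplexSpec(n_residues_per_chain=(5, 5), interface_residues=(), seed=0)
    )
    antigen = select_chains(st, {"A"})
    rids = antigen.residue_ids()
    m = PairScoreMatrix(
        rows=[("H", 27, ""), ("H", 28, "")],
        cols=rids,
        scores=np.full((2, len(rids)), 0.5),
    )
    row, col, _ = m.argmax
    assert row == ("H", 27, "") and col == rids[0]
    with pytest.warns(UserWarning, match="clamped"):
        patch = predict_epitope_patch(m, antigen, top_k=99, neighbor_radius=8.0)
    assert patch["contiguous"] is False  # 10 Å ladder spacing exceeds 8 Å


def test_site_overlap_arithmetic():
    assert site_overlap({1, 2, 3}, {1, 2, 3}) == (3, 1.0)
    assert site_overlap({1, 2}, {3, 4}) == (2 - 2, 0.0)
    inter, jac = site_overlap(set(range(1, 11)), set(range(6, 16)))
    assert inter == 5
    assert jac == pytest.approx(5 / 15)
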
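"""Decoy generation, fnat, pose features and the pose discriminator."""

import numpy as np
import pytest

from reepitope.pose import (
    DockPose,
    extract_pose_features,
    fnat,
    generate_decoys,
    label_pose,
    pose_feature_names,
    screen_antibody_panel,
    train_pose_classifier,
)
from reepitope.structure import select_chains
from reepitope.synthetic import ToyComplexSpec, make_toy_complex


def test_decoy_generation_is_seed_deterministic(toy_complex):
    st, _ = toy_complex
    a = generate_decoys(st, {"B"}, {"A"}, 10, 10, perturb=(2.0, 0.5), seed=1)
    b = generate_decoys(st, {"B"}, {"A"}, 10, 10, perturb=(2.0, 0.5), seed=1)
    for p, q in zip(a, b):
        assert np.allclose(p.rotation, q.rotation)
        assert np.allclose(p.translation, q.translation)


def test_small_perturbations_keep_native_contacts(toy_complex):
    st, _ = toy_complex
    near = generate_decoys(st, {"B"}, {"A"}, 10, 0, perturb=(2.0, 0.5), seed=4)
    assert all(fnat(p, st) > 0.5 for p in near)


def test_far_decoys_have_zero_fnat_and_no_clashes(toy_complex):
    st, _ = toy_complex
    far = generate_decoys(st, {"B"}, {"A"}, 0, 10, seed=4)
    from scipy.spatial import cKDTree

    ag = select_chains(st, {"A"})
    for p in far:
        assert fnat(p, st) == 0.0
        d, _ = cKDTree(ag.coords).query(p.placed_antibody().coords)
        assert d.min() >= 2.0


def test_rigid_transform_preserves_internal_distances(toy_complex):
    st, _ = toy_complex
    poses = generate_decoys(st, {"B"}, {"A"}, 3, 3, seed=0)
    base = select_chains(st, {"B"}).coords
    d_base = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
    for p in poses:
        c = p.placed_antibody().coords
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        assert np.abs(d - d_base).max() < 1e-6


def test_fnat_identity_pose_is_one(toy_complex):
    st, _ = toy_complex
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.zeros(3),
    )
    assert fnat(pose, st) == 1.0


def test_fnat_translated_far_is_zero(toy_complex):
    st, _ = toy_complex
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.array([0.0, 50.0, 0.0]),
    )
    assert fnat(pose, st) == 0.0


def test_fnat_partial_preservation_three_quarters():
    native, _ = make_toy_complex(ToyComplexSpec(interface_residues=(0, 1, 2, 3), seed=6))
    moved, _ = make_toy_complex(ToyComplexSpec(interface_residues=(0, 1, 2), seed=6))
    pose = DockPose(
        antigen=select_chains(native, {"A"}),
        antibody=select_chains(moved, {"B"}),  # residue 4 displaced out of contact
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.zeros(3),
    )
    assert fnat(pose, native) == 0.75


def test_fnat_empty_native_contacts_errors():
    st, _ = make_toy_complex(ToyComplexSpec(interface_residues=(), seed=6))
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.zeros(3),
    )
    with pytest.raises(ValueError, match="empty"):
        fnat(pose, st)


def test_pose_labels_follow_thresholds():
    assert label_pose(0.8).cls == "native_like"
    assert label_pose(0.05).cls == "decoy"
    assert label_pose(0.3).cls == "ambiguous"


def test_zero_interface_features_are_neutral(toy_complex):
    st, _ = toy_complex
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.array([0.0, 100.0, 0.0]),
    )
    f = extract_pose_features(pose)
    names = pose_feature_names()
    assert len(f) == len(names)
    assert f[names.index("n_interface_residues")] == 0
    assert f[names.index("buried_area")] == 0
    comp = f[2:42]
    assert np.all(comp == 0)
    assert f[names.index("score_percentile")] == 0.5


def test_interface_composition_pure_residues():
    spec = ToyComplexSpec(
        n_residues_per_chain=(4, 4),
        interface_residues=(0, 1, 2, 3),
        sequence_a="AAAA",
        sequence_b="GGGG",
        seed=0,
    )
    st, _ = make_toy_complex(spec)
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.zeros(3),
    )
    f = extract_pose_features(pose)
    names = pose_feature_names()
    assert f[names.index("comp_ag_A")] == pytest.approx(1.0)  # antigen side all ALA
    assert f[names.index("comp_ab_G")] == pytest.approx(1.0)  # antibody side all GLY


def test_engine_score_rank_and_percentile(toy_complex):
    st, _ = toy_complex
    pose = DockPose(
        antigen=select_chains(st, {"A"}),
        antibody=select_chains(st, {"B"}),
        rotation=np.array([0.0, 0.0, 0.0, 1.0]),
        translation=np.zeros(3),
        engine_score=9.0,
    )
    f = extract_pose_features(pose, run_scores=[1.0, 5.0, 9.0])
    names = pose_feature_names()
    assert f[names.index("score_rank")] == 1
    assert f[names.index("score_percentile")] == pytest.approx(1.0)


def test_planted_signal_classifier_auc(pose_dataset):
    X, y, groups = pose_dataset
    forest, report = train_pose_classifier(X, y, groups, n_trees=100, seed=0, folds=4)
    assert report["pooled_auc"] >= 0.9
    # interface-size features carry the planted signal
    names = pose_feature_names()
    top3 = [names[i] for i in np.argsort(-forest.model.feature_importances_)[:3]]
    assert {"n_interface_residues", "buried_area"} & set(top3)


def test_shuffled_labels_fall_in_null_band(pose_dataset):
    X, y, groups = pose_dataset
    shuffled = np.random.default_rng(0).permutation(y)
    _, report = train_pose_classifier(X, shuffled, groups, n_trees=100, seed=0, folds=4)
    assert 0.35 <= report["pooled_auc"] <= 0.65


def test_perfectly_separating_feature_gives_auc_one():
    rng = np.random.default_rng(0)
    n = 80
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, 3))
    X[:, 0] = y * 10.0 + rng.normal(scale=0.1, size=n)
    groups = np.repeat([f"g{i}" for i in range(4)], n // 4)
    _, report = train_pose_classifier(X, y, groups, n_trees=100, seed=0, folds=4)
    assert report["pooled_auc"] == 1.0


def test_single_class_input_rejected(pose_dataset):
    X, y, groups = pose_dataset
    with pytest.raises(ValueError, match="both classes"):
        train_pose_classifier(X, np.ones_like(y), groups, n_trees=10, folds=4)


def test_panel_screen_ranks_true_binder_first(pose_dataset, toy_complex):
    X, y, groups = pose_dataset
    forest, _ = train_pose_classifier(X, y, groups, n_trees=100, seed=0, folds=4)
    st, _ = toy_complex
    antigen = select_chains(st, {"A"})
    binder = select_chains(st, {"B"})
    decoy_st, _ = make_toy_complex(
        ToyComplexSpec(n_residues_per_chain=(8, 8), interface_residues=(), seed=77)
    )
    nonbinder = select_chains(decoy_st, {"B"})
    near = generate_decoys(st, {"B"}, {"A"}, 5, 0, perturb=(2.0, 0.5), seed=1)
    results = screen_antibody_panel(
        [("binder", binder), ("nonbinder", nonbinder)],
        antigen,
        forest,
        poses_per_antibody=5,
        seed=2,
        supplied_poses={"binder": near},
    )
    assert results[0]["antibody_id"] == "binder"
    assert results[0]["implied_epitope"]  # epitope residues reported
    # determinism
    results2 = screen_antibody_panel(
        [("binder", binder), ("nonbinder", nonbinder)],
        antigen,
        forest,
        poses_per_antibody=5,
        seed=2,
        supplied_poses={"binder": near},
    )
    assert [(r["antibody_id"], r["score"]) for r in results] == [
        (r["antibody_id"], r["score"]) for r in results2
    ]


def test_panel_of_one(pose_dataset, toy_complex):
    X, y, groups = pose_dataset
    forest, _ = train_pose_classifier(X, y, groups, n_trees=50, seed=0, folds=4)
    st, _ = toy_complex
    results = screen_antibody_panel(
        [("only", select_chains(st, {"B"}))],
        select_chains(st, {"A"}),
        forest,
        poses_per_antibody=3,
        seed=0,
    )
    assert len(results) == 1 and results[0]["antibody_id"] == "only"
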
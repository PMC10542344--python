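"""Docking-pose discrimination: decoy generation, fnat labelling, interface
featurization and random-forest classification of native-like poses.

The docking engine itself is out of scope: poses are rigid-body placements
supplied by the caller or produced by the decoy generator (small
perturbations of the native placement, and uniform random placements on a
sphere around the antigen with clash rejection).  The classifier consumes
interface properties — surface size, amino-acid composition, specific
interactions — plus the pose's standing in its docking run's score
distribution.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import GroupKFold

from .interface import contact_residues, interface_area
from .structure import ComplexStructure, ResidueId, select_chains, three_to_one

__all__ = [
    "DockPose",
    "PoseLabel",
    "TrainedForest",
    "FEATURE_SCHEMA_VERSION",
    "generate_decoys",
    "fnat",
    "label_pose",
    "extract_pose_features",
    "pose_feature_names",
    "train_pose_classifier",
    "screen_antibody_panel",
]

FEATURE_SCHEMA_VERSION = "pose-features-1"
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# heavy-atom surrogates for hydrogen-bond capability and formal charge
_POLAR_ELEMENTS = {"N", "O"}
_POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclasses.dataclass
class DockPose:
    """A rigid-body placement of an antibody relative to a fixed antigen."""

    antigen: ComplexStructure
    antibody: ComplexStructure  # reference frame before the transform
    rotation: np.ndarray  # unit quaternion (x, y, z, w)
    translation: np.ndarray  # Å
    engine_score: float | None = None
    pose_id: str = ""

    def placed_antibody(self) -> ComplexStructure:
        R = Rotation.from_quat(self.rotation).as_matrix()
        return self.antibody.transformed(R, self.translation)

    def complex(self) -> ComplexStructure:
        placed = self.placed_antibody()
        return ComplexStructure(
            list(self.antigen.atoms) + list(placed.atoms),
            title="pose",
            source_id=self.pose_id,
        )


@dataclasses.dataclass(frozen=True)
class PoseLabel:
    fnat: float
    cls: str  # native_like | decoy | ambiguous


def label_pose(
    fnat_value: float, native_min: float = 0.5, decoy_max: float = 0.1
) -> PoseLabel:
    """Classify a pose by fraction of native contacts (thresholds configurable)."""
    if fnat_value >= native_min:
        cls = "native_like"
    elif fnat_value <= decoy_max:
        cls = "decoy"
    else:
        cls = "ambiguous"
    return PoseLabel(fnat=fnat_value, cls=cls)


def _identity_pose(native, antibody_chains, antigen_chains) -> tuple[ComplexStructure, ComplexStructure]:
    antigen = select_chains(native, set(antigen_chains))
    antibody = select_chains(native, set(antibody_chains))
    return antigen, antibody


def generate_decoys(
    native: ComplexStructure,
    antibody_chains: Iterable[str],
    antigen_chains: Iterable[str],
    n_near: int,
    n_far: int,
    perturb: tuple[float, float] = (5.0, 1.0),
    seed: int = 0,
    clash_distance: float = 2.0,
    max_tries: int = 500,
) -> list[DockPose]:
    """Near-native and random decoy poses around a native complex.

    Near poses rotate the antibody about its centroid by up to
    ``perturb[0]`` degrees and translate by up to ``perturb[1]`` Å.  Far
    poses place a randomly oriented antibody on a sphere around the antigen,
    rejecting placements with any heavy-atom pair closer than
    ``clash_distance``.
    """
    antibody_chains = set(antibody_chains)
    antigen_chains = set(antigen_chains)
    antigen, antibody = _identity_pose(native, antibody_chains, antigen_chains)
    if len(contact_residues(native, antibody_chains, antigen_chains)) == 0:
        raise ValueError("native complex has no interface at 5 Å")
    rng = np.random.default_rng(seed)
    max_rot_deg, max_trans = perturb
    poses: list[DockPose] = []

    ab_centroid = antibody.coords.mean(axis=0)
    ag_centroid = antigen.coords.mean(axis=0)
    r_ab = np.linalg.norm(antibody.coords - ab_centroid, axis=1).max()
    r_ag = np.linalg.norm(antigen.coords - ag_centroid, axis=1).max()
    ag_tree = cKDTree(antigen.coords)

    def _random_unit(rng) -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for i in range(n_near):
        axis = _random_unit(rng)
        angle = np.deg2rad(rng.uniform(0.0, max_rot_deg))
        rot = Rotation.from_rotvec(axis * angle)
        shift = _random_unit(rng) * rng.uniform(0.0, max_trans)
        # rotate about the antibody centroid, then translate
        t = ab_centroid - rot.as_matrix() @ ab_centroid + shift
        poses.append(
            DockPose(
                antigen=antigen,
                antibody=antibody,
                rotation=rot.as_quat(),
                translation=t,
                pose_id=f"near_{i:03d}",
            )
        )

    for i in range(n_far):
        for attempt in range(max_tries):
            rot = Rotation.random(rng=rng)
            direction = _random_unit(rng)
            dist = r_ag + r_ab + rng.uniform(1.0, 10.0)
            target_centroid = ag_centroid + direction * dist
            t = target_centroid - rot.as_matrix() @ ab_centroid
            new_coords = antibody.coords @ rot.as_matrix().T + t
            d, _ = ag_tree.query(new_coords, k=1)
            if d.min() >= clash_distance:
                poses.append(
                    DockPose(
                        antigen=antigen,
                        antibody=antibody,
                        rotation=rot.as_quat(),
                        translation=t,
                        pose_id=f"far_{i:03d}",
                    )
                )
                break
        else:
            raise RuntimeError(
                f"no clash-free far pose in {max_tries} tries "
                f"(antigen radius {r_ag:.1f} Å, antibody radius {r_ab:.1f} Å)"
            )
    return poses


def fnat(pose: DockPose, native: ComplexStructure, cutoff: float = 5.0) -> float:
    """Fraction of native inter-chain residue contacts preserved by the pose."""
    ab_chains = pose.antibody.chain_ids()
    ag_chains = pose.antigen.chain_ids()
    native_contacts = contact_residues(native, ab_chains, ag_chains, cutoff).pairs
    if not native_contacts:
        raise ValueError("native contact set is empty")
    pose_contacts = contact_residues(pose.complex(), ab_chains, ag_chains, cutoff).pairs
    preserved = sum(1 for p in native_contacts if p in pose_contacts)
    return preserved / len(native_contacts)


def pose_feature_names() -> list[str]:
    names = ["n_interface_residues", "buried_area"]
    names += [f"comp_ab_{a}" for a in AA_ORDER]
    names += [f"comp_ag_{a}" for a in AA_ORDER]
    names += ["hbond_pairs", "charge_pairs"]
    names += ["score_rank", "score_z", "score_percentile"]
    return names


def _interface_composition(
    structure: ComplexStructure, residues: set[ResidueId]
) -> np.ndarray:
    counts = np.zeros(20)
    for rid in residues:
        aa = three_to_one(structure.residue_name(rid))
        if aa in AA_ORDER:
            counts[AA_ORDER.index(aa)] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def extract_pose_features(
    pose: DockPose,
    run_scores: Sequence[float] = (),
    cutoff: float = 5.0,
    sasa_points: int = 120,
) -> np.ndarray:
    """Fixed-schema feature vector for one pose (see ``pose_feature_names``).

    With no engine scores the score-distribution block is set to neutral
    constants (rank 0, z 0.0, percentile 0.5).
    """
    cplx = pose.complex()
    ab_chains = pose.antibody.chain_ids()
    ag_chains = pose.antigen.chain_ids()
    contacts = contact_residues(cplx, ab_chains, ag_chains, cutoff)
    ab_res = contacts.side_a_residues
    ag_res = contacts.side_b_residues
    n_iface = len(ab_res) + len(ag_res)
    if n_iface > 0:
        buried = interface_area(
            cplx, ab_chains, ag_chains, n_points=sasa_points
        ).delta_sasa
    else:
        buried = 0.0

    comp_ab = _interface_composition(cplx, ab_res)
    comp_ag = _interface_composition(cplx, ag_res)

    # specific interactions across the interface
    ab_atoms = [a for a in cplx.atoms if a.chain_id in ab_chains]
    ag_atoms = [a for a in cplx.atoms if a.chain_id in ag_chains]
    hbond = charge = 0
    if ab_atoms and ag_atoms:
        ab_xyz = np.array([a.coordinates for a in ab_atoms])
        ag_xyz = np.array([a.coordinates for a in ag_atoms])
        tree = cKDTree(ag_xyz)
        for i, a in enumerate(ab_atoms):
            for j in tree.query_ball_point(ab_xyz[i], 4.0):
                b = ag_atoms[j]
                d = np.linalg.norm(ab_xyz[i] - ag_xyz[j])
                if (
                    d <= 3.5
                    and a.element in _POLAR_ELEMENTS
                    and b.element in _POLAR_ELEMENTS
                ):
                    hbond += 1
                ka = (a.residue_name, a.atom_name)
                kb = (b.residue_name, b.atom_name)
                if d <= 4.0 and (
                    (ka in _POSITIVE_ATOMS and kb in _NEGATIVE_ATOMS)
                    or (ka in _NEGATIVE_ATOMS and kb in _POSITIVE_ATOMS)
                ):
                    charge += 1

    if len(run_scores) > 0 and pose.engine_score is not None:
        scores = np.asarray(run_scores, dtype=float)
        rank = int(1 + np.sum(scores > pose.engine_score))
        std = scores.std()
        z = float((pose.engine_score - scores.mean()) / std) if std > 0 else 0.0
        percentile = float(np.mean(scores <= pose.engine_score))
    else:
        rank, z, percentile = 0, 0.0, 0.5

    return np.concatenate(
        [
            [n_iface, buried],
            comp_ab,
            comp_ag,
            [hbond, charge],
            [rank, z, percentile],
        ]
    )


@dataclasses.dataclass
class TrainedForest:
    """A fitted random-forest classifier plus its feature schema and metadata."""

    model: RandomForestClassifier
    schema_version: str
    metadata: dict

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != self.model.n_features_in_:
            raise ValueError(
                f"feature schema mismatch: model expects "
                f"{self.model.n_features_in_} features, got {features.shape[1]}"
            )
        return self.model.predict_proba(features)[:, 1]


def train_pose_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    groups: Sequence[str],
    n_trees: int = 500,
    max_depth: int | None = None,
    seed: int = 0,
    folds: int = 4,
) -> tuple[TrainedForest, dict]:
    """Grouped cross-validation and final fit of the pose discriminator.

    ``groups`` are source-complex identifiers; no complex spans folds.
    Returns the forest refit on all data plus a report with per-fold and
    pooled AUC/accuracy.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    if len(np.unique(groups)) < folds:
        raise ValueError(
            f"need at least {folds} source complexes for {folds}-fold grouped CV"
        )

    def _forest() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )

    fold_aucs, fold_accs = [], []
    pooled_scores, pooled_labels = [], []
    for train_idx, test_idx in GroupKFold(n_splits=folds).split(features, labels, groups):
        if len(np.unique(labels[train_idx])) < 2 or len(np.unique(labels[test_idx])) < 2:
            raise ValueError("a fold lost one of the classes; stratify your decoy sets")
        clf = _forest().fit(features[train_idx], labels[train_idx])
        prob = clf.predict_proba(features[test_idx])[:, 1]
        fold_aucs.append(float(roc_auc_score(labels[test_idx], prob)))
        fold_accs.append(float(accuracy_score(labels[test_idx], prob >= 0.5)))
        pooled_scores.append(prob)
        pooled_labels.append(labels[test_idx])
    pooled_auc = float(
        roc_auc_score(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
    )
    final = _forest().fit(features, labels)
    report = {
        "fold_aucs": fold_aucs,
        "fold_accuracies": fold_accs,
        "pooled_auc": pooled_auc,
        "n_folds": folds,
    }
    forest = TrainedForest(
        model=final,
        schema_version=FEATURE_SCHEMA_VERSION,
        metadata={"seed": seed, "n_trees": n_trees, "folds": folds},
    )
    return forest, report


def screen_antibody_panel(
    antibodies: Sequence[tuple[str, ComplexStructure]],
    antigen: ComplexStructure,
    model: TrainedForest,
    poses_per_antibody: int = 20,
    seed: int = 0,
    supplied_poses: dict[str, list[DockPose]] | None = None,
    cutoff: float = 5.0,
) -> list[dict]:
    """Rank candidate template antibodies docked against one antigen.

    Per antibody the best classifier score over its poses is retained; the
    panel is sorted descending by best score (ties: antibody id).  Each hit
    reports the implied epitope — antigen residues within ``cutoff`` of the
    best pose.
    """
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise ValueError(
            f"model schema {model.schema_version} != {FEATURE_SCHEMA_VERSION}"
        )
    rng = np.random.default_rng(seed)
    results = []
    for ab_id, antibody in antibodies:
        if supplied_poses and ab_id in supplied_poses:
            poses = supplied_poses[ab_id]
        else:
            poses = _random_panel_poses(
                antibody, antigen, poses_per_antibody, rng
            )
        feats = np.array([extract_pose_features(p) for p in poses])
        scores = model.score(feats)
        best = int(np.argmax(scores))
        best_pose = poses[best]
        epi = contact_residues(
            best_pose.complex(),
            antibody.chain_ids(),
            antigen.chain_ids(),
            cutoff,
        ).side_b_residues
        results.append(
            {
                "antibody_id": ab_id,
                "best_pose": best_pose,
                "score": float(scores[best]),
                "implied_epitope": sorted(epi),
            }
        )
    results.sort(key=lambda r: (-r["score"], r["antibody_id"]))
    return results


def _random_panel_poses(antibody, antigen, n, rng) -> list[DockPose]:
    ab_centroid = antibody.coords.mean(axis=0)
    ag_centroid = antigen.coords.mean(axis=0)
    r_ab = np.linalg.norm(antibody.coords - ab_centroid, axis=1).max()
    r_ag = np.linalg.norm(antigen.coords - ag_centroid, axis=1).max()
    ag_tree = cKDTree(antigen.coords)
    poses = []
    tries = 0
    while len(poses) < n and tries < n * 100:
        tries += 1
        rot = Rotation.random(rng=rng)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        dist = rng.uniform(max(2.0, r_ag + r_ab - 6.0), r_ag + r_ab + 6.0)
        t = ag_centroid + v * dist - rot.as_matrix() @ ab_centroid
        coords = antibody.coords @ rot.as_matrix().T + t
        d, _ = ag_tree.query(coords, k=1)
        if d.min() >= 2.0:
            poses.append(
                DockPose(
                    antigen=antigen,
                    antibody=antibody,
                    rotation=rot.as_quat(),
                    translation=t,
                    pose_id=f"panel_{len(poses):03d}",
                )
            )
    if len(poses) < n:
        raise RuntimeError("could not generate enough clash-free panel poses")
    return poses
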
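"""Pairwise antibody-position × antigen-residue interaction scoring.

Given a corpus of antibody–antigen complexes, every (antibody position,
antigen residue) pair is a training example labelled by whether the pair is
in contact at 5 Å.  Per-chain random forests are trained with grouped
fourfold cross-validation (no complex contributes pairs to more than one
fold).  For a query antibody sequence and an antigen structure, all pairs
against exposed antigen residues are scored and the top-scoring pairs define
a predicted epitope patch.

The corpus curation rules: resolution strictly better than 3.0 Å, protein
antigen, no single-chain antibodies; redundancy between two entries means
antigen sequence identity > 95% together with antigen-binding-region (ABR)
sequence identity > 85%, and within a redundant group only the
best-resolution entry survives (ties break to the lexicographically first
entry id).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import AnnotatedAntibody
from .pose import TrainedForest, train_pose_classifier  # forest plumbing reused
from .sasa import atom_radii, shrake_rupley
from .structure import ComplexStructure, ResidueId, three_to_one

__all__ = [
    "CorpusEntry",
    "PairScoreMatrix",
    "PAIR_SCHEMA_VERSION",
    "curate_corpus",
    "build_pair_dataset",
    "crossval_pair_classifier",
    "score_all_pairs",
    "predict_epitope_patch",
    "site_overlap",
    "pair_feature_names",
]

PAIR_SCHEMA_VERSION = "pair-features-1"
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_REGIONS = ["FR", "CDR1", "CDR2", "CDR3"]

_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_KD_HYDRO = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}


@dataclasses.dataclass
class CorpusEntry:
    """One antibody–antigen complex prepared for pair-level training.

    ``ab_positions`` lists (chain_type, region, residue) per antibody
    position index; ``labeled_pairs`` are true 5 Å contacts as
    (antibody position index, antigen residue index).
    """

    entry_id: str
    resolution: float
    antigen_type: str  # protein | peptide | hapten | other
    is_single_chain_antibody: bool
    antigen_seq: str
    abr_seqs: str
    ab_positions: list[tuple[str, str, str]]
    labeled_pairs: set[tuple[int, int]]
    antigen_exposure: list[float] | None = None


@dataclasses.dataclass
class PairScoreMatrix:
    rows: list[tuple[str, int, str]]  # antibody position keys
    cols: list[ResidueId]  # exposed antigen residues
    scores: np.ndarray  # (rows, cols), probabilities

    @property
    def argmax(self) -> tuple[tuple[str, int, str], ResidueId, float]:
        # deterministic tie-break: lowest row index, then column index
        flat = np.round(self.scores, 12)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        best = flat[i, j]
        ties = np.argwhere(flat == best)
        i, j = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
        return self.rows[i], self.cols[j], float(self.scores[i, j])


def _seq_identity(a: str, b: str) -> float:
    """Percent identity over alignment columns of a global alignment."""
    if not a or not b:
        return 0.0
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    aln = al.align(a, b)[0]
    matches = 0
    for (rs, re), (qs, _) in zip(*aln.aligned):
        matches += sum(1 for k in range(re - rs) if a[rs + k] == b[qs + k])
    return 100.0 * matches / max(len(a), len(b))


def curate_corpus(entries: Sequence[CorpusEntry]) -> list[CorpusEntry]:
    """Apply the resolution / antigen-type / redundancy curation rules."""
    kept = [
        e
        for e in entries
        if e.resolution < 3.0
        and e.antigen_type == "protein"
        and not e.is_single_chain_antibody
    ]
    # union-find over the redundancy relation
    parent = {e.entry_id: e.entry_id for e in kept}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if (
                _seq_identity(a.antigen_seq, b.antigen_seq) > 95.0
                and _seq_identity(a.abr_seqs, b.abr_seqs) > 85.0
            ):
                ra, rb = find(a.entry_id), find(b.entry_id)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[CorpusEntry]] = {}
    for e in kept:
        groups.setdefault(find(e.entry_id), []).append(e)
    survivors = [
        min(group, key=lambda e: (e.resolution, e.entry_id))
        for group in groups.values()
    ]
    return sorted(survivors, key=lambda e: e.entry_id)


def pair_feature_names() -> list[str]:
    names = [f"ab_{a}" for a in AA_ORDER]
    names += [f"ag_{a}" for a in AA_ORDER]
    names += [f"region_{r}" for r in _REGIONS]
    names += ["ag_exposure"]
    for off in (-2, -1, 1, 2):
        names += [f"ctx{off:+d}_{a}" for a in AA_ORDER]
    names += ["charge_product", "hydro_product", "volume_sum"]
    return names


def _one_hot(aa: str) -> np.ndarray:
    v = np.zeros(20)
    if aa in AA_ORDER:
        v[AA_ORDER.index(aa)] = 1.0
    return v


def _pair_features(
    ab_res: str,
    ab_region: str,
    ag_seq: str,
    ag_idx: int,
    exposure: float,
) -> np.ndarray:
    ag_res = ag_seq[ag_idx]
    region = ab_region if ab_region in _REGIONS else "FR"
    region_vec = np.array([1.0 if region == r else 0.0 for r in _REGIONS])
    ctx = []
    for off in (-2, -1, 1, 2):
        k = ag_idx + off
        ctx.append(_one_hot(ag_seq[k]) if 0 <= k < len(ag_seq) else np.zeros(20))
    phys = np.array(
        [
            _CHARGE.get(ab_res, 0.0) * _CHARGE.get(ag_res, 0.0),
            _KD_HYDRO.get(ab_res, 0.0) * _KD_HYDRO.get(ag_res, 0.0),
            _VOLUME.get(ab_res, 0.0) + _VOLUME.get(ag_res, 0.0),
        ]
    )
    return np.concatenate(
        [_one_hot(ab_res), _one_hot(ag_res), region_vec, [exposure], *ctx, phys]
    )


def build_pair_dataset(
    corpus: Sequence[CorpusEntry],
    negative_subsample_ratio: float = 1.0,
    seed: int = 0,
) -> dict:
    """Feature matrix + labels over all (antibody position, antigen residue)
    pairs, with non-contact pairs subsampled per entry at the stated ratio.

    Returns a dict with ``X``, ``y``, ``groups`` (entry ids), ``chains``
    (chain type per row) and ``feature_names``.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)
    X, y, groups, chains = [], [], [], []
    for entry in corpus:
        if not entry.labeled_pairs:
            warnings.warn(f"entry {entry.entry_id} has no contact pairs; skipped")
            continue
        exposure = entry.antigen_exposure or [0.5] * len(entry.antigen_seq)
        negatives = [
            (i, j)
            for i in range(len(entry.ab_positions))
            for j in range(len(entry.antigen_seq))
            if (i, j) not in entry.labeled_pairs
        ]
        n_neg = int(round(negative_subsample_ratio * len(entry.labeled_pairs)))
        n_neg = min(n_neg, len(negatives))
        chosen = (
            [negatives[k] for k in rng.choice(len(negatives), n_neg, replace=False)]
            if n_neg
            else []
        )
        for (i, j), label in [(p, 1) for p in sorted(entry.labeled_pairs)] + [
            (p, 0) for p in chosen
        ]:
            chain_type, region, residue = entry.ab_positions[i]
            X.append(_pair_features(residue, region, entry.antigen_seq, j, exposure[j]))
            y.append(label)
            groups.append(entry.entry_id)
            chains.append("H" if chain_type == "H" else "L")
    return {
        "X": np.array(X),
        "y": np.array(y),
        "groups": np.array(groups),
        "chains": np.array(chains),
        "feature_names": pair_feature_names(),
    }


def crossval_pair_classifier(
    dataset: Mapping,
    chain: str = "heavy",
    folds: int = 4,
    n_trees: int = 300,
    max_depth: int | None = None,
    seed: int = 0,
) -> tuple[TrainedForest, dict]:
    """Grouped k-fold CV (entries never span folds) + final fit, per chain."""
    want = "H" if chain in ("heavy", "H") else "L"
    sel = dataset["chains"] == want
    X, y, groups = dataset["X"][sel], dataset["y"][sel], dataset["groups"][sel]
    if len(np.unique(groups)) < folds:
        raise ValueError(
            f"{len(np.unique(groups))} source entries < {folds} folds"
        )
    forest, report = train_pose_classifier(
        X, y, groups, n_trees=n_trees, max_depth=max_depth, seed=seed, folds=folds
    )
    forest.schema_version = PAIR_SCHEMA_VERSION
    report["chain"] = chain
    return forest, report


def antigen_surface_residues(
    antigen: ComplexStructure,
    exposure_threshold: float = 0.05,
    n_points: int = 240,
) -> tuple[list[ResidueId], dict[ResidueId, float]]:
    """Exposed antigen residues and their relative side-chain-free exposure.

    Relative exposure = residue SASA / (a generous 200 Å² full-exposure
    scale), clipped to [0, 1]; residues below the threshold are buried.
    """
    radii = atom_radii([a.element for a in antigen.atoms])
    sasa = shrake_rupley(antigen.coords, radii, n_points=n_points)
    by_res = antigen.atom_indices_by_residue()
    exposure = {
        rid: float(min(1.0, sasa[idx].sum() / 200.0)) for rid, idx in by_res.items()
    }
    exposed = [rid for rid in antigen.residue_ids() if exposure[rid] >= exposure_threshold]
    return exposed, exposure


def score_all_pairs(
    antibody: AnnotatedAntibody,
    antigen: ComplexStructure,
    model: TrainedForest,
    exposure_threshold: float = 0.05,
) -> PairScoreMatrix:
    """Score every (antibody position, exposed antigen residue) pair."""
    if model.schema_version != PAIR_SCHEMA_VERSION:
        raise ValueError(
            f"model schema {model.schema_version} != {PAIR_SCHEMA_VERSION}"
        )
    cols, exposure = antigen_surface_residues(antigen, exposure_threshold)
    ag_rids_all = antigen.residue_ids()
    ag_seq = "".join(three_to_one(antigen.residue_name(r)) for r in ag_rids_all)
    col_index = {rid: k for k, rid in enumerate(ag_rids_all)}

    rows = []
    feats = []
    for chain in ("H", "L"):
        for pos in antibody.positions(chain):
            rows.append(pos.key)
            for rid in cols:
                j = col_index[rid]
                region = pos.region if pos.region.startswith("CDR") else "FR"
                feats.append(
                    _pair_features(pos.residue, region, ag_seq, j, exposure[rid])
                )
    scores = model.score(np.array(feats)).reshape(len(rows), len(cols))
    return PairScoreMatrix(rows=rows, cols=cols, scores=scores)


def predict_epitope_patch(
    matrix: PairScoreMatrix,
    antigen: ComplexStructure,
    top_k: int = 10,
    neighbor_radius: float = 8.0,
) -> dict:
    """Epitope patch from the top-scoring pairs of a score matrix.

    The seed patch is the antigen residues of the ``top_k`` pairs (ties break
    to lowest row then column index); it is expanded with spatial neighbours
    drawn from the next tier of top-scoring columns.  The report carries the
    mean supporting-pair score and a surface-contiguity flag (every member
    within ``neighbor_radius`` of another member).
    """
    n_pairs = matrix.scores.size
    if top_k > n_pairs:
        warnings.warn(f"top_k {top_k} exceeds matrix size {n_pairs}; clamped")
        top_k = n_pairs
    order = np.argsort(-matrix.scores, axis=None, kind="stable")
    top = [np.unravel_index(int(k), matrix.scores.shape) for k in order[: 3 * top_k]]
    seed_pairs = top[:top_k]
    seed_res = {matrix.cols[j] for _, j in seed_pairs}
    candidate_res = {matrix.cols[j] for _, j in top}

    centroids = {}
    by_res = antigen.atom_indices_by_residue()
    for rid in candidate_res:
        centroids[rid] = antigen.coords[by_res[rid]].mean(axis=0)
    patch = set(seed_res)
    for rid in candidate_res - seed_res:
        if any(
            np.linalg.norm(centroids[rid] - centroids[s]) <= neighbor_radius
            for s in seed_res
        ):
            patch.add(rid)

    pts = np.array([centroids.get(r, antigen.coords[by_res[r]].mean(axis=0)) for r in patch])
    contiguous = True
    if len(patch) > 1:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        contiguous = bool((d[:, 1] <= neighbor_radius).all())
    mean_score = float(
        np.mean([matrix.scores[i, j] for i, j in seed_pairs]) if seed_pairs else 0.0
    )
    return {
        "residues": sorted(patch),
        "supporting_pairs": [
            (matrix.rows[i], matrix.cols[j], float(matrix.scores[i, j]))
            for i, j in seed_pairs
        ],
        "mean_score": mean_score,
        "contiguous": contiguous,
    }


def site_overlap(patch_a: set, patch_b: set) -> tuple[int, float]:
    """Intersection size and Jaccard index of two antigen residue sets."""
    inter = len(set(patch_a) & set(patch_b))
    union = len(set(patch_a) | set(patch_b))
    return inter, (inter / union if union else 0.0)
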
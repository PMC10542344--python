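"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pytest

from reepitope.pairwise import build_pair_dataset
from reepitope.pose import extract_pose_features, fnat, generate_decoys, label_pose
from reepitope.synthetic import (
    ToyComplexSpec,
    make_pair_corpus,
    make_toy_antibody,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def toy_complex():
    """8+8-residue ladder with four planted contact pairs."""
    return make_toy_complex(ToyComplexSpec(interface_residues=(0, 2, 4, 6), seed=3))


@pytest.fixture(scope="session")
def toy_antibody_clean():
    """Toy Fv identical to its germline over the covered span."""
    return make_toy_antibody(seed=1, n_mutations_from_germline=0)


@pytest.fixture(scope="session")
def toy_antibody_mutated():
    """Toy Fv with three planted heavy-chain mutations."""
    return make_toy_antibody(seed=2, n_mutations_from_germline=3)


@pytest.fixture(scope="session")
def pair_dataset():
    """Planted-signal pair dataset over 10 synthetic complexes."""
    corpus = make_pair_corpus(10, signal=([("R", "E"), ("K", "D")], 10.0), seed=0)
    return build_pair_dataset(corpus, negative_subsample_ratio=1.0, seed=0)


@pytest.fixture(scope="session")
def pose_dataset():
    """Near/far decoy features over 8 toy complexes, fnat-labelled."""
    X, y, groups = [], [], []
    for c in range(8):
        st, _ = make_toy_complex(
            ToyComplexSpec(n_residues_per_chain=(8, 8), interface_residues=(0, 2, 4, 6), seed=10 + c)
        )
        poses = generate_decoys(
            st, {"B"}, {"A"}, n_near=12, n_far=12, perturb=(3.0, 0.8), seed=c
        )
        for p in poses:
            lab = label_pose(fnat(p, st))
            if lab.cls == "ambiguous":
                continue
            X.append(extract_pose_features(p))
            y.append(1 if lab.cls == "native_like" else 0)
            groups.append(f"cplx{c}")
    return np.array(X), np.array(y), np.array(groups)
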
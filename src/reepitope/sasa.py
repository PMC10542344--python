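"""Shrake–Rupley solvent-accessible surface area.

A sphere of quasi-uniform test points (Fibonacci lattice) is placed on each
atom at the expanded radius (vdW + probe); points falling inside any
neighbouring expanded sphere are occluded.  SASA of an atom is the accessible
fraction of its expanded-sphere area.  Radii are element-keyed (Chothia/NACCESS
convention, shipped as package data); probe radius defaults to 1.4 Å.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["atom_radii", "shrake_rupley", "accessible_points", "DEFAULT_PROBE"]

DEFAULT_PROBE = 1.4


def _load_radii() -> tuple[dict[str, float], float]:
    text = resources.files("reepitope.data").joinpath("sasa_radii.json").read_text()
    table = json.loads(text)
    return {k.upper(): float(v) for k, v in table["radii"].items()}, float(table["default"])


_RADII, _RADII_DEFAULT = _load_radii()


def atom_radii(elements: list[str]) -> np.ndarray:
    """vdW radii (Å) for a list of element symbols."""
    return np.array([_RADII.get(e.upper(), _RADII_DEFAULT) for e in elements])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _accessibility_mask(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int
) -> np.ndarray:
    """(n_atoms, n_points) boolean mask of solvent-accessible test points."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    expanded = radii + probe
    unit = fibonacci_sphere(n_points)
    mask = np.ones((n, n_points), dtype=bool)
    if n == 0:
        return mask
    tree = cKDTree(coords)
    max_exp = expanded.max()
    for i in range(n):
        nbrs = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_exp) if j != i]
        if not nbrs:
            continue
        nbrs = np.array(nbrs)
        close = np.linalg.norm(coords[nbrs] - coords[i], axis=1) < expanded[i] + expanded[nbrs]
        nbrs = nbrs[close]
        if nbrs.size == 0:
            continue
        pts = coords[i] + expanded[i] * unit  # (P, 3)
        d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
        occluded = (d2 < (expanded[nbrs] ** 2)[None, :]).any(axis=1)
        mask[i] = ~occluded
    return mask


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²).

    Doubling ``n_points`` changes an isolated sphere's area by well under 1%;
    960 points is the reporting default, smaller counts are used where SASA is
    only a machine-learning feature.
    """
    radii = np.asarray(radii, dtype=float)
    mask = _accessibility_mask(np.asarray(coords, float), radii, probe, n_points)
    expanded = radii + probe
    frac = mask.mean(axis=1)
    return frac * 4.0 * np.pi * expanded**2


def accessible_points(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 240,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accessible surface dots with outward normals.

    Accessibility is judged at the probe-expanded radius (standard SASA
    geometry) but the dots themselves are placed on the van der Waals
    sphere, so the facing dot surfaces of two sides in atomic contact nearly
    touch.  Returns ``(points, normals, atom_index)``; used by the
    shape-complementarity statistic.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    mask = _accessibility_mask(coords, radii, probe, n_points)
    unit = fibonacci_sphere(n_points)
    pts_list, nrm_list, idx_list = [], [], []
    for i in range(len(coords)):
        sel = mask[i]
        if not sel.any():
            continue
        pts_list.append(coords[i] + radii[i] * unit[sel])
        nrm_list.append(unit[sel])
        idx_list.append(np.full(sel.sum(), i))
    if not pts_list:
        return np.empty((0, 3)), np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(pts_list), np.vstack(nrm_list), np.concatenate(idx_list)
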
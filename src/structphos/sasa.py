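"""Solvent-accessible surface area by deterministic sphere-point sampling.

Rolling-probe (Shrake-Rupley) ASA: each heavy atom is expanded by the probe
radius (water, 1.4 Angstrom) and covered with a fixed golden-spiral point
set; a point is accessible when it lies outside every other expanded atom.
The point set is deterministic (no RNG), so identical inputs give identical
areas.  With 960 points per atom the area is accurate to roughly 1 A^2.

Relative accessibility normalises the residue sum by the residue type's
maximum ASA in an extended Gly-X-Gly context (theoretical values of
Tien et al. 2013); unknown types fall back to the table mean and are
flagged as imputed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from structphos.structure import ProteinStructure, Residue

VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70

# Theoretical maximum ASA (A^2) per residue type, Gly-X-Gly extended.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
_MEAN_MAX_ASA = float(np.mean(list(MAX_ASA.values())))


def sphere_points(n: int = 960) -> np.ndarray:
    """Deterministic unit-sphere covering via the golden-section spiral."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def shrake_rupley(
    s: ProteinStructure, probe: float = 1.4, n_points: int = 960
) -> dict[tuple[str, str], float]:
    """Absolute per-residue ASA (A^2) for every residue of the structure."""
    residues = s.residues()
    coords, radii, owner = [], [], []
    for idx, r in enumerate(residues):
        for a in r.heavy_atoms:
            coords.append(a.coord)
            radii.append(atom_radius(a.element))
            owner.append(idx)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    owner = np.asarray(owner)
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max() + probe
    areas = np.zeros(len(residues))
    for i in range(len(coords)):
        ri = radii[i] + probe
        surface = coords[i] + ri * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            rj = radii[j] + probe
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            accessible &= d2 > rj * rj
        frac = accessible.mean()
        areas[owner[i]] += frac * 4.0 * np.pi * ri * ri
    return {residues[i].key: float(areas[i]) for i in range(len(residues))}


def solvent_accessibility(
    s: ProteinStructure,
    r: Residue,
    probe: float = 1.4,
    n_points: int = 960,
    _cache: dict | None = None,
) -> tuple[float, float, bool]:
    """(absolute ASA, relative ASA, imputed-flag) for one residue.

    ``_cache`` lets callers reuse a precomputed :func:`shrake_rupley` map
    when iterating over many residues of the same structure.
    """
    areas = _cache if _cache is not None else shrake_rupley(s, probe, n_points)
    absolute = areas[r.key]
    imputed = r.aa not in MAX_ASA
    max_asa = MAX_ASA.get(r.aa, _MEAN_MAX_ASA)
    return absolute, absolute / max_asa, imputed
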
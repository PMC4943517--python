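"""Structural neighborhoods: Euclidean sphere and Voronoi/Delaunay adjacency.

Two neighbor definitions drive the neighborhood features.  The Euclidean
graph connects residues whose minimum heavy-atom distance is at most a
cutoff (10 Angstrom by default, boundary inclusive).  The Voronoi graph
connects residues when at least one heavy atom of each shares a Voronoi
facet -- equivalently, when the two atoms are joined by a Delaunay edge of
the atom-level tessellation.  A separate tessellation of side-chain
centroids underlies the four-body pseudo-potential.

Tessellations use Qhull (scipy.spatial.Delaunay).  Degenerate point sets
(coplanar, cospherical) are retried once with a deterministic jitter of
magnitude 1e-6 Angstrom seeded from the coordinates themselves.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from structphos.errors import DegenerateGeometryError
from structphos.structure import ProteinStructure, Residue, side_chain_centroid

ResidueKey = tuple[str, str]


@dataclass
class EuclideanNeighborGraph:
    """Per-residue neighbor sets with minimum heavy-atom distances."""

    cutoff: float
    adjacency: dict[ResidueKey, dict[ResidueKey, float]] = field(default_factory=dict)

    def neighbors(self, key: ResidueKey) -> dict[ResidueKey, float]:
        return self.adjacency.get(key, {})

    def degree(self, key: ResidueKey) -> int:
        return len(self.adjacency.get(key, {}))

    def to_edge_rows(self) -> list[tuple[str, str, str, str, float]]:
        rows = []
        for (c1, s1), nbrs in self.adjacency.items():
            for (c2, s2), d in nbrs.items():
                if (c1, s1) < (c2, s2):
                    rows.append((c1, s1, c2, s2, d))
        return rows


@dataclass
class VoronoiNeighborGraph:
    """Per-residue Voronoi-adjacent residue sets plus atom-edge multiplicities.

    ``edge_counts[k]`` is the number of distinct atom-level Delaunay edges
    leaving residue ``k`` toward atoms of other residues; together with the
    residue degree it forms the two-slot 'Voronoi contacts' site feature.
    """

    adjacency: dict[ResidueKey, set[ResidueKey]] = field(default_factory=dict)
    edge_counts: dict[ResidueKey, int] = field(default_factory=dict)

    def neighbors(self, key: ResidueKey) -> set[ResidueKey]:
        return self.adjacency.get(key, set())

    def degree(self, key: ResidueKey) -> int:
        return len(self.adjacency.get(key, set()))

    def to_edge_rows(self) -> list[tuple[str, str, str, str, str]]:
        rows = []
        for (c1, s1), nbrs in self.adjacency.items():
            for c2, s2 in nbrs:
                if (c1, s1) < (c2, s2):
                    rows.append((c1, s1, c2, s2, "NA"))
        return rows


@dataclass
class Tessellation:
    points: np.ndarray  # (n, 3)
    tetrahedra: np.ndarray  # (m, 4) indices into points
    point_refs: list | None = None  # optional per-point residue keys
    point_aas: list | None = None  # optional per-point one-letter codes

    def incident(self, point_index: int) -> np.ndarray:
        """Row indices of tetrahedra containing the given point."""
        return np.nonzero((self.tetrahedra == point_index).any(axis=1))[0]


def euclidean_neighbor_graph(s: ProteinStructure, cutoff: float = 10.0) -> EuclideanNeighborGraph:
    """Residues i,j are neighbors iff min heavy-atom distance <= cutoff, i != j."""
    residues = s.residues()
    coords = []
    owner = []
    for idx, r in enumerate(residues):
        for a in r.heavy_atoms:
            coords.append(a.coord)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    graph = EuclideanNeighborGraph(cutoff=cutoff)
    for r in residues:
        graph.adjacency[r.key] = {}
    if len(coords) < 2:
        return graph
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    best: dict[tuple[int, int], float] = {}
    for a, b in pairs:
        ra, rb = owner[a], owner[b]
        if ra == rb:
            continue
        if ra > rb:
            ra, rb = rb, ra
        d = float(np.linalg.norm(coords[a] - coords[b]))
        key = (int(ra), int(rb))
        if d < best.get(key, np.inf):
            best[key] = d
    for (ra, rb), d in best.items():
        ka, kb = residues[ra].key, residues[rb].key
        graph.adjacency[ka][kb] = d
        graph.adjacency[kb][ka] = d
    return graph


def _jitter_seed(points: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(points, dtype=np.float64).tobytes()) % (2**31)


def delaunay_tetrahedra(
    points: np.ndarray,
    point_refs: list | None = None,
    max_edge: float | None = None,
    jitter_on_failure: bool = True,
) -> Tessellation:
    """Delaunay tessellation of 3-D points into tetrahedra.

    ``max_edge`` optionally prunes tetrahedra with any edge longer than the
    threshold (off by default).  Degenerate inputs are retried once with a
    deterministic 1e-6 Angstrom jitter; if that also fails a
    :class:`DegenerateGeometryError` is raised.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise DegenerateGeometryError(f"need >=4 3-D points, got shape {pts.shape}")
    try:
        tri = Delaunay(pts)
    except QhullError:
        if not jitter_on_failure:
            raise DegenerateGeometryError("degenerate point set (coplanar?)") from None
        rng = np.random.default_rng(_jitter_seed(pts))
        try:
            tri = Delaunay(pts + rng.normal(scale=1e-6, size=pts.shape))
        except QhullError as exc:
            raise DegenerateGeometryError("degenerate point set (coplanar?)") from exc
    tets = tri.simplices
    if tets.shape[1] != 4:
        raise DegenerateGeometryError("tessellation did not produce tetrahedra")
    if max_edge is not None:
        keep = []
        for row in tets:
            edges_ok = True
            for i in range(4):
                for j in range(i + 1, 4):
                    if np.linalg.norm(pts[row[i]] - pts[row[j]]) > max_edge:
                        edges_ok = False
                        break
                if not edges_ok:
                    break
            keep.append(edges_ok)
        tets = tets[np.asarray(keep, dtype=bool)]
    return Tessellation(points=pts, tetrahedra=np.array(tets), point_refs=point_refs)


def voronoi_neighbor_graph(
    s: ProteinStructure, max_edge: float | None = None
) -> VoronoiNeighborGraph:
    """Residue adjacency from the atom-level Delaunay tessellation.

    Two residues are adjacent iff some heavy atom of one shares a Delaunay
    edge (equivalently a Voronoi facet, in generic position) with some heavy
    atom of the other.  Atom pairs within the same residue contribute no edge.
    """
    residues = s.residues()
    coords = []
    owner = []
    for idx, r in enumerate(residues):
        for a in r.heavy_atoms:
            coords.append(a.coord)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    if len(coords) < 4:
        raise DegenerateGeometryError("need >=4 heavy atoms for a tessellation")
    tess = delaunay_tetrahedra(coords, max_edge=max_edge)
    graph = VoronoiNeighborGraph()
    for r in residues:
        graph.adjacency[r.key] = set()
        graph.edge_counts[r.key] = 0
    atom_edges: set[tuple[int, int]] = set()
    for row in tess.tetrahedra:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(row[i]), int(row[j])
                if owner[a] == owner[b]:
                    continue
                atom_edges.add((min(a, b), max(a, b)))
    for a, b in atom_edges:
        ra, rb = residues[owner[a]], residues[owner[b]]
        graph.adjacency[ra.key].add(rb.key)
        graph.adjacency[rb.key].add(ra.key)
        graph.edge_counts[ra.key] += 1
        graph.edge_counts[rb.key] += 1
    return graph


def centroid_tessellation(
    s: ProteinStructure, max_edge: float | None = None
) -> Tessellation:
    """Delaunay tessellation of side-chain centroids (one point per residue)."""
    residues = s.residues()
    pts = np.array([side_chain_centroid(r) for r in residues])
    tess = delaunay_tetrahedra(pts, point_refs=[r.key for r in residues], max_edge=max_edge)
    tess.point_aas = [r.aa for r in residues]
    return tess


def residue_index(s: ProteinStructure) -> dict[ResidueKey, Residue]:
    return {r.key: r for r in s.residues()}
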
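"""Neighbor graphs and Delaunay tessellation against brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog

from structphos.errors import DegenerateGeometryError
from structphos.neighborhoods import (
    centroid_tessellation,
    delaunay_tetrahedra,
    euclidean_neighbor_graph,
    voronoi_neighbor_graph,
)
from structphos.structure import min_heavy_atom_distance
from tests.conftest import point_structure


def delaunay_edge_oracle(points: np.ndarray, i: int, j: int, tol: float = 1e-9) -> bool:
    """Is (i, j) a Delaunay edge? LP feasibility of an empty circumsphere.

    Lifting-map formulation: the edge is Delaunay iff some affine function
    h(x) = a.x + b satisfies h = |x|^2 on both endpoints and h <= |x|^2 - t
    (t > 0) on every other point; h encodes a sphere through i and j with
    the others strictly outside.
    """
    n = len(points)
    sq = (points**2).sum(axis=1)
    # variables: a (3), b, t ; maximize t  (linprog minimizes -t), cap t <= 1
    c = np.zeros(5)
    c[4] = -1.0
    A_eq = np.zeros((2, 5))
    b_eq = np.zeros(2)
    for row, idx in enumerate((i, j)):
        A_eq[row, :3] = points[idx]
        A_eq[row, 3] = 1.0
        b_eq[row] = sq[idx]
    others = [k for k in range(n) if k not in (i, j)]
    A_ub = np.zeros((len(others), 5))
    b_ub = np.zeros(len(others))
    for row, k in enumerate(others):
        A_ub[row, :3] = points[k]
        A_ub[row, 3] = 1.0
        A_ub[row, 4] = 1.0
        b_ub[row] = sq[k]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * 4 + [(None, 1.0)], method="highs",
    )
    return res.success and res.x[4] > tol


def circumsphere(p):
    """Center and radius of the sphere through 4 points."""
    a = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    center = np.linalg.solve(a, b)
    return center, np.linalg.norm(p[0] - center)


class TestEuclideanGraph:
    @pytest.mark.parametrize(
        "distance,expected", [(9.9, True), (10.0, True), (10.1, False)]
    )
    def test_cutoff_boundary_inclusive(self, distance, expected):
        s = point_structure([(0, 0, 0), (distance, 0, 0)])
        g = euclidean_neighbor_graph(s)
        assert (("A", "2") in g.neighbors(("A", "1"))) is expected

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        s = point_structure(rng.uniform(0, 18, size=(25, 3)))
        g = euclidean_neighbor_graph(s, cutoff=10.0)
        residues = s.residues()
        for a in residues:
            for b in residues:
                if a.key == b.key:
                    assert b.key not in g.neighbors(a.key)
                    continue
                d = min_heavy_atom_distance(a, b)
                assert (b.key in g.neighbors(a.key)) == (d <= 10.0)
                if b.key in g.neighbors(a.key):
                    assert g.neighbors(a.key)[b.key] == pytest.approx(d)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        s = point_structure(rng.uniform(0, 15, size=(15, 3)))
        g = euclidean_neighbor_graph(s)
        for k, nbrs in g.adjacency.items():
            for k2 in nbrs:
                assert k in g.adjacency[k2]


class TestDelaunay:
    def test_four_points_one_tetrahedron(self):
        t = delaunay_tetrahedra(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]))
        assert len(t.tetrahedra) == 1

    def test_coplanar_raises_without_jitter(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            delaunay_tetrahedra(pts, jitter_on_failure=False)

    def test_empty_circumsphere_property(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(10, 3))
        t = delaunay_tetrahedra(pts)
        for row in t.tetrahedra:
            center, radius = circumsphere(pts[row])
            others = [k for k in range(len(pts)) if k not in row]
            dists = np.linalg.norm(pts[others] - center, axis=1)
            assert (dists > radius - 1e-6).all()

    def test_max_edge_filter_bounds_edges(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 20, size=(30, 3))
        t = delaunay_tetrahedra(pts, max_edge=8.0)
        for row in t.tetrahedra:
            for i in range(4):
                for j in range(i + 1, 4):
                    assert np.linalg.norm(pts[row[i]] - pts[row[j]]) <= 8.0


class TestVoronoiGraph:
    def test_tetrahedron_connects_all_pairs(self, tetra_structure):
        g = voronoi_neighbor_graph(tetra_structure)
        keys = [r.key for r in tetra_structure.residues()]
        for a in keys:
            assert g.neighbors(a) == set(keys) - {a}

    def test_adjacency_matches_circumsphere_oracle(self):
        """Atom-level Delaunay adjacency equals the LP empty-circumsphere oracle."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(6, 13))
            pts = rng.uniform(0, 10, size=(n, 3))
            s = point_structure(pts)
            g = voronoi_neighbor_graph(s)
            keys = [r.key for r in s.residues()]
            for i in range(n):
                for j in range(i + 1, n):
                    expected = delaunay_edge_oracle(pts, i, j)
                    got = keys[j] in g.neighbors(keys[i])
                    assert got == expected, (trial, i, j)

    def test_symmetric(self):
        rng = np.random.default_rng(8)
        s = point_structure(rng.uniform(0, 12, size=(12, 3)))
        g = voronoi_neighbor_graph(s)
        for k, nbrs in g.adjacency.items():
            for k2 in nbrs:
                assert k in g.adjacency[k2]

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, size=(12, 3))
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        g1 = voronoi_neighbor_graph(point_structure(pts))
        g2 = voronoi_neighbor_graph(point_structure(moved))
        assert g1.adjacency == g2.adjacency

    def test_edge_rows_exportable(self, tetra_structure):
        eg = euclidean_neighbor_graph(tetra_structure)
        vg = voronoi_neighbor_graph(tetra_structure)
        erows = eg.to_edge_rows()
        assert len(erows) == 6  # all pairs within 10 A
        assert all(isinstance(r[4], float) for r in erows)
        vrows = vg.to_edge_rows()
        assert len(vrows) == 6 and all(r[4] == "NA" for r in vrows)

    def test_centroid_tessellation_carries_letters(self, tetra_structure):
        t = centroid_tessellation(tetra_structure)
        assert t.point_aas == ["A", "S", "T", "Y"]
        assert len(t.tetrahedra) == 1
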
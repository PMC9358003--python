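"""Weighted Delaunay triangulation: orthospheres, lifting, interior test."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from poreflow import AtomSet, orthosphere, weighted_delaunay
from poreflow.alpha_complex import INFINITY, orthospheres_batch
from poreflow.errors import DegeneracyError, SizeError

from conftest import random_atoms


def brute_force_regular_tets(points, weights, tol=1e-9):
    """All 4-subsets whose orthosphere is empty (power distance >= -tol to
    every other point): the regular triangulation by definition."""
    n = len(points)
    quads = np.array(list(itertools.combinations(range(n), 4)))
    p = points[quads]
    w = weights[quads]
    vol = np.abs(np.einsum("ij,ij->i",
                           np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                           p[:, 3] - p[:, 0])) / 6
    ok = vol > 1e-12
    centers, sq = orthospheres_batch(p[ok], w[ok])
    keep = []
    for quad, c, s in zip(quads[ok], centers, sq):
        others = np.setdiff1d(np.arange(n), quad)
        power = np.sum((points[others] - c) ** 2, axis=1) - weights[others]
        if np.all(power >= s - tol):
            keep.append(tuple(sorted(quad)))
    return set(keep)


REG_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)


class TestOrthosphere:
    def test_unit_weight_regular_tetrahedron(self):
        # circumradius R = sqrt(3); unit weights shift the power by 1
        center, sq = orthosphere(REG_TET, np.ones(4))
        np.testing.assert_allclose(center, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(sq, 3.0 - 1.0, atol=1e-12)

    def test_equal_weights_give_unweighted_circumcenter(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        c0, _ = orthosphere(pts, np.zeros(4))
        cw, _ = orthosphere(pts, np.full(4, 2.7))
        np.testing.assert_allclose(c0, cw, atol=1e-9)
        # equal distance to all four vertices
        d = np.linalg.norm(pts - c0, axis=1)
        np.testing.assert_allclose(d, d[0], atol=1e-9)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegeneracyError):
            orthosphere(pts, np.ones(4))

    def test_center_has_equal_power_to_all_vertices(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(4, 3)) * 3
        w = rng.uniform(0.5, 4.0, 4)
        center, sq = orthosphere(pts, w)
        power = np.sum((pts - center) ** 2, axis=1) - w
        np.testing.assert_allclose(power, sq, atol=1e-9)


class TestWeightedDelaunay:
    def test_four_corners_plus_centroid(self):
        # unit weights: regular triangulation = classical Delaunay; the
        # centroid splits the tetrahedron into 4, all sharing it
        pts = np.vstack([2.0 * REG_TET, [[0.0, 0.0, 0.0]]])
        atoms = AtomSet(pts, np.ones(5))
        t = weighted_delaunay(atoms, probe=0.0)
        assert t.n_tets == 4
        assert all(4 in quad for quad in t.tets)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        atoms = random_atoms(25, seed)
        t = weighted_delaunay(atoms, probe=0.0)
        got = {tuple(sorted(q)) for q in t.tets}
        expected = brute_force_regular_tets(t.points, t.weights)
        assert got == expected

    def test_empty_orthosphere_property(self):
        atoms = random_atoms(40, seed=5)
        t = weighted_delaunay(atoms, probe=1.0)
        for quad, c, s in zip(t.tets, t.orthocenters, t.sq_orthoradius):
            others = np.setdiff1d(np.arange(len(t.points)), quad)
            power = np.sum((t.points[others] - c) ** 2, axis=1) - t.weights[others]
            assert np.all(power >= s - 1e-9)

    def test_coplanar_points_degenerate(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(8, 2)),
                               np.zeros(8)])
        with pytest.raises(DegeneracyError):
            weighted_delaunay(AtomSet(pts, np.ones(8)), probe=0.0)

    def test_too_few_atoms(self):
        with pytest.raises(SizeError):
            weighted_delaunay(AtomSet(np.eye(3), np.ones(3)), probe=0.0)

    def test_scaling_invariance(self):
        atoms = random_atoms(30, seed=9)
        t1 = weighted_delaunay(atoms, probe=0.0)
        s = 3.7
        # scale after the (scale-dependent) jitter would differ; compare the
        # triangulation of pre-scaled input instead
        scaled = AtomSet(atoms.centers * s, atoms.radii * s)
        t2 = weighted_delaunay(scaled, probe=0.0)
        assert {tuple(sorted(q)) for q in t1.tets} == {tuple(sorted(q)) for q in t2.tets}
        np.testing.assert_allclose(t2.orthocenters, t1.orthocenters * s, atol=1e-3)
        np.testing.assert_allclose(t2.sq_orthoradius, t1.sq_orthoradius * s**2,
                                   rtol=1e-4, atol=1e-3)

    def test_adjacency_and_volume_invariants(self):
        atoms = random_atoms(50, seed=13)
        t = weighted_delaunay(atoms, probe=0.5)
        # every face shared by <= 2 tets; internal faces exactly 2; hull 1
        from collections import Counter

        faces = Counter()
        for quad in t.tets:
            for k in range(4):
                faces[tuple(sorted(np.delete(quad, k)))] += 1
        assert set(faces.values()) <= {1, 2}
        n_hull_faces = sum(1 for v in faces.values() if v == 1)
        assert n_hull_faces == int(np.sum(t.neighbors == INFINITY))
        # tets tile the convex hull
        hull = ConvexHull(t.points)
        assert abs(t.volumes.sum() - hull.volume) / hull.volume < 1e-6

    def test_interior_flag_sign_convention(self):
        # two heavily overlapping balls plus far-away padding: the tets
        # spanning the overlap region are interior (negative orthoradius)
        pts = np.array([
            [0, 0, 0], [0.8, 0, 0],
            [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 10],
        ], float)
        radii = np.array([1.5, 1.5, 0.1, 0.1, 0.1, 0.1])
        t = weighted_delaunay(AtomSet(pts, radii), probe=0.0)
        pair_tets = [i for i, q in enumerate(t.tets) if 0 in q and 1 in q]
        assert pair_tets, "expected tets on the overlapping pair"
        # far-apart tiny balls: any tet avoiding the overlapping pair is not interior
        for i, q in enumerate(t.tets):
            if 0 not in q and 1 not in q:
                assert not t.interior[i]

    def test_determinism(self):
        atoms = random_atoms(30, seed=21)
        t1 = weighted_delaunay(atoms, probe=1.4)
        t2 = weighted_delaunay(atoms, probe=1.4)
        np.testing.assert_array_equal(t1.tets, t2.tets)
        np.testing.assert_array_equal(t1.points, t2.points)
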
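"""Centerline path, Frenet frames, local radius, radius profiles."""

from __future__ import annotations

import numpy as np
import pytest

from poreflow import (
    SkeletonGraph,
    compute_centerline,
    frenet_from_points,
    local_radius,
    radius_profile,
)
from poreflow.errors import ConnectivityError, ValidationError


def helix_points(a=5.0, b=2.0, step=0.25, turns=2.0):
    arc = np.hypot(a, b)
    s = np.arange(0.0, 2 * np.pi * turns * arc, step)
    t = s / arc
    return np.column_stack([a * np.cos(t), a * np.sin(t), b * t]), step


class TestFrenet:
    def test_helix_closed_form(self):
        pts, step = helix_points()
        _, _, _, kappa, tau, defined = frenet_from_points(pts, step)
        core = slice(10, -10)
        k_true, t_true = 5 / 29, 2 / 29
        assert np.median(kappa[core]) == pytest.approx(k_true, rel=0.05)
        assert np.median(tau[core]) == pytest.approx(t_true, rel=0.05)
        assert defined[core].all()

    def test_planar_circle(self):
        R = 7.0
        s = np.arange(0, 2 * np.pi * R, 0.25)
        pts = np.column_stack([R * np.cos(s / R), R * np.sin(s / R),
                               np.zeros_like(s)])
        _, _, _, kappa, tau, _ = frenet_from_points(pts, 0.25)
        assert np.median(kappa[5:-5]) == pytest.approx(1 / R, rel=0.02)
        assert np.abs(tau[5:-5]).max() < 1e-6

    def test_straight_line_flagged(self):
        pts = np.column_stack([np.arange(0, 10, 0.5), np.zeros(20), np.zeros(20)])
        tangents, _, _, kappa, tau, defined = frenet_from_points(pts, 0.5)
        assert kappa.max() < 1e-9
        assert np.all(tau == 0)
        assert not defined.any()
        np.testing.assert_allclose(np.linalg.norm(tangents, axis=1), 1.0,
                                   atol=1e-9)

    def test_tangents_unit_norm(self):
        pts, step = helix_points()
        tangents, *_ = frenet_from_points(pts, step)
        np.testing.assert_allclose(np.linalg.norm(tangents, axis=1), 1.0,
                                   atol=1e-9)


def _ladder_graph(n=30, wobble=0.0, seed=0):
    """Straight chain along z plus an off-axis parallel chain with low
    clearance, to exercise the clearance-weighted cost."""
    rng = np.random.default_rng(seed)
    z = np.linspace(0, 15, n)
    main = np.column_stack([np.zeros(n), np.zeros(n), z])
    side = np.column_stack([np.full(n, 2.0), np.zeros(n), z])
    pos = np.vstack([main, side]) + rng.normal(scale=wobble, size=(2 * n, 3))
    clearance = np.concatenate([np.full(n, 4.0), np.full(n, 0.5)])
    edges = [(i, i + 1) for i in range(n - 1)]
    edges += [(n + i, n + i + 1) for i in range(n - 1)]
    edges += [(i, n + i) for i in range(n)]
    return SkeletonGraph(pos, clearance, np.array(edges))


class TestComputeCenterline:
    def test_follows_high_clearance_chain(self):
        g = _ladder_graph()
        cl = compute_centerline(g, 0, 29, step=0.5)
        assert np.abs(cl.points[:, 0]).max() < 0.5

    def test_source_equals_target_error(self):
        g = _ladder_graph()
        with pytest.raises(ConnectivityError):
            compute_centerline(g, 3, 3)

    def test_disconnected_error(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [5, 5, 5], [6, 5, 5]], float)
        g = SkeletonGraph(pos, np.ones(4), np.array([[0, 1], [2, 3]]))
        with pytest.raises(ConnectivityError):
            compute_centerline(g, 0, 3)

    def test_reversal_symmetry(self, cylinder_skeleton, cylinder_channel_surface):
        from poreflow import prune_skeleton

        path = prune_skeleton(cylinder_skeleton)
        s, t = int(path.node_ids[0]), int(path.node_ids[-1])
        a = compute_centerline(cylinder_skeleton, s, t, step=0.5)
        b = compute_centerline(cylinder_skeleton, t, s, step=0.5)
        np.testing.assert_allclose(a.points, b.points[::-1], atol=1e-6)
        np.testing.assert_allclose(a.tangents, -b.tangents[::-1], atol=1e-6)
        np.testing.assert_allclose(a.curvature, b.curvature[::-1], atol=1e-6)
        np.testing.assert_allclose(np.abs(a.torsion),
                                   np.abs(b.torsion[::-1]), atol=1e-6)
        ra = local_radius(a, cylinder_channel_surface)
        rb = local_radius(b, cylinder_channel_surface)
        np.testing.assert_allclose(ra, rb[::-1], atol=1e-6)

    def test_resampling_invariance(self, cylinder_skeleton):
        from poreflow import prune_skeleton

        path = prune_skeleton(cylinder_skeleton)
        s, t = int(path.node_ids[0]), int(path.node_ids[-1])
        a = compute_centerline(cylinder_skeleton, s, t, step=0.5)
        b = compute_centerline(cylinder_skeleton, s, t, step=0.25)
        assert abs(a.arclength[-1] - b.arclength[-1]) / a.arclength[-1] < 0.01

    def test_spacing_within_bounds(self, cylinder_centerline):
        gaps = np.diff(cylinder_centerline.arclength)
        assert np.all(gaps > 0.2 * 0.5 - 1e-9)
        assert np.all(gaps < 2.0 * 0.5 + 1e-9)


class TestLocalRadius:
    def test_matches_brute_force(self, cylinder_centerline,
                                 cylinder_channel_surface):
        import copy

        cl = copy.copy(cylinder_centerline)
        rng = np.random.default_rng(0)
        sel = rng.choice(len(cl.points), size=min(50, len(cl.points)),
                         replace=False)
        fast = local_radius(cl, cylinder_channel_surface)
        verts = cylinder_channel_surface.vertices()
        brute = np.linalg.norm(
            cl.points[sel][:, None] - verts[None], axis=2).min(axis=1)
        np.testing.assert_allclose(fast[sel], brute, atol=1e-9)

    def test_point_on_surface_radius_near_zero(self, cylinder_channel_surface,
                                               cylinder_centerline):
        import copy

        cl = copy.copy(cylinder_centerline)
        v = cylinder_channel_surface.vertices()[0]
        cl.points = np.vstack([cl.points[:4], v])
        r = local_radius(cl, cylinder_channel_surface)
        assert r[-1] < 0.5  # below mesh spacing


class TestRadiusProfile:
    def test_constant_radius_zero_sd(self):
        z = np.linspace(-5, 5, 40)
        frames = [(z, np.full_like(z, 3.0))] * 3
        prof = radius_profile(frames, bin_width=1.0)
        assert (prof["sd"] == 0).all()
        assert (prof["mean_radius"] == 3.0).all()

    def test_two_frames_hand_statistics(self):
        z = np.array([0.4])
        prof = radius_profile([(z, np.array([2.0])), (z, np.array([4.0]))],
                              bin_width=1.0)
        assert len(prof) == 1
        assert prof.loc[0, "mean_radius"] == pytest.approx(3.0)
        assert prof.loc[0, "sd"] == pytest.approx(np.sqrt(2.0))
        assert prof.loc[0, "n"] == 2

    def test_single_wide_bin(self):
        z = np.linspace(0.1, 0.9, 10)
        prof = radius_profile([(z, np.ones(10))], bin_width=100.0)
        assert len(prof) == 1
        assert prof.loc[0, "n"] == 10

    def test_empty_input_error(self):
        with pytest.raises(ValidationError):
            radius_profile([], bin_width=1.0)
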
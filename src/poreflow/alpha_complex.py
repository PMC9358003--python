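"""Weighted Delaunay (regular) triangulation and alpha-complex interior test.

A molecule is a union of balls; each atom center carries the weight
``(radius + probe)**2``.  The regular triangulation is obtained by the
standard lifting: ``(x, y, z)`` with weight ``w`` maps to
``(x, y, z, x^2 + y^2 + z^2 - w)`` and the lower convex-hull facets in 4D
project to the tetrahedra.  A tetrahedron belongs to the molecule (the alpha
complex at alpha = 0) iff its signed squared orthoradius is <= 0.

Degenerate configurations (cospherical/coplanar subsets) are resolved by a
deterministic jitter of at most 1e-6 Angstrom whose seed is derived from the
atom count, so identical inputs always yield identical triangulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegeneracyError, SizeError
from .structure_io import AtomSet

#: Sentinel neighbor id for convex-hull faces ("point at infinity" side).
INFINITY = -1

JITTER_SCALE = 1e-6

#: Roundoff band: tetrahedra with sq_orthoradius in (0, INTERIOR_TOL] are
#: treated as interior.
INTERIOR_TOL = 1e-9


@dataclass
class Tetrahedralization:
    """Weighted Delaunay triangulation of (jittered) atom centers.

    ``neighbors[t, k]`` is the tetrahedron across the face opposite vertex
    ``tets[t, k]``, or :data:`INFINITY` for a convex-hull face.
    """

    points: np.ndarray            # (n, 3) effective (jittered) coordinates
    weights: np.ndarray           # (n,) (radius + probe)^2
    tets: np.ndarray              # (T, 4) vertex ids, positively oriented
    neighbors: np.ndarray         # (T, 4) neighbor ids or INFINITY
    orthocenters: np.ndarray      # (T, 3)
    sq_orthoradius: np.ndarray    # (T,) signed
    redundant: np.ndarray         # vertex ids absent from every tetrahedron
    probe: float = 0.0
    interior: np.ndarray | None = None   # (T,) bool, set by classify_interior

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @cached_property
    def volumes(self) -> np.ndarray:
        v = self.points[self.tets]
        return np.abs(
            np.einsum("ij,ij->i",
                      np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                      v[:, 3] - v[:, 0])
        ) / 6.0

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    def hull_volume(self) -> float:
        return float(ConvexHull(self.points).volume)

    def inflated_radii(self) -> np.ndarray:
        return np.sqrt(self.weights)


def deterministic_jitter(centers: np.ndarray, scale: float = JITTER_SCALE) -> np.ndarray:
    """Uniform perturbation of at most ``scale`` per coordinate, seeded from
    the atom count only (identical inputs -> identical jitter)."""
    n = len(centers)
    seed = (n * 2654435761) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    return centers + rng.uniform(-scale, scale, size=centers.shape)


def orthosphere(points: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and signed squared radius of the sphere orthogonal to four
    weighted points (equal power distance to all four).

    The power of a point ``x`` w.r.t. ball ``(c, w)`` is ``|x - c|^2 - w``;
    the orthocenter is the unique point with equal power to all four balls
    and the returned ``sq_radius`` is that common power (may be negative).
    """
    p = np.asarray(points, float).reshape(4, 3)
    w = np.asarray(weights, float).reshape(4)
    a = 2.0 * (p[1:] - p[0])
    vol6 = abs(np.linalg.det(p[1:] - p[0]))
    if vol6 / 6.0 < 1e-12:
        raise DegeneracyError("degenerate tetrahedron (volume < 1e-12)")
    rhs = (np.sum(p[1:] ** 2, axis=1) - w[1:]) - (np.sum(p[0] ** 2) - w[0])
    center = np.linalg.solve(a, rhs)
    sq_radius = float(np.sum((center - p[0]) ** 2) - w[0])
    return center, sq_radius


def orthospheres_batch(p: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`orthosphere` for ``p`` (T, 4, 3) and ``w`` (T, 4)."""
    a = 2.0 * (p[:, 1:] - p[:, :1])
    rhs = (np.sum(p[:, 1:] ** 2, axis=2) - w[:, 1:]) - (
        np.sum(p[:, :1] ** 2, axis=2) - w[:, :1]
    )
    centers = np.linalg.solve(a, rhs[..., None])[..., 0]
    sq = np.sum((centers - p[:, 0]) ** 2, axis=1) - w[:, 0]
    return centers, sq


def weighted_delaunay(atoms: AtomSet, probe: float = 1.4) -> Tetrahedralization:
    """Regular triangulation of atoms with weights ``(r + probe)^2``.

    Raises :class:`SizeError` for fewer than five atoms and
    :class:`DegeneracyError` for coplanar input.  Redundant atoms (whose
    power cell is empty) simply do not appear in any tetrahedron and are
    reported in ``redundant``.
    """
    if probe < 0:
        raise ValueError("probe must be >= 0")
    n = len(atoms)
    if n < 5:
        raise SizeError(f"need >= 5 atoms for a weighted Delaunay triangulation, got {n}")
    # degeneracy test on the raw input: jitter cannot rescue a coplanar set
    span = np.linalg.svd(atoms.centers - atoms.centers.mean(axis=0),
                         compute_uv=False)
    if span[-1] < 1e-8 * max(span[0], 1.0):
        raise DegeneracyError("all points (nearly) coplanar")
    pts = deterministic_jitter(atoms.centers)
    weights = (atoms.radii + probe) ** 2

    lifted = np.column_stack([pts, np.sum(pts**2, axis=1) - weights])
    try:
        hull = ConvexHull(lifted, qhull_options="Qt")
    except QhullError as exc:
        raise DegeneracyError(f"convex hull of lifted points failed: {exc}") from exc

    lower = hull.equations[:, 3] < -1e-10
    tets = hull.simplices[lower]
    if len(tets) == 0:
        raise DegeneracyError("no lower facets: degenerate lifted hull")

    # consistent positive orientation
    v = pts[tets]
    signed6 = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    )
    flip = signed6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    # drop exactly-flat slivers Qt may emit on cospherical leftovers
    keep = np.abs(signed6) > 1e-14
    tets = tets[keep]

    neighbors = _face_adjacency(tets)
    centers, sq = orthospheres_batch(pts[tets], weights[tets])
    used = np.zeros(n, dtype=bool)
    used[tets.ravel()] = True
    redundant = np.flatnonzero(~used)

    t = Tetrahedralization(
        points=pts,
        weights=weights,
        tets=tets,
        neighbors=neighbors,
        orthocenters=centers,
        sq_orthoradius=sq,
        redundant=redundant,
        probe=probe,
    )
    classify_interior(t)
    return t


def _face_adjacency(tets: np.ndarray) -> np.ndarray:
    """Neighbor array from shared faces; INFINITY marks hull faces."""
    T = len(tets)
    neighbors = np.full((T, 4), INFINITY, dtype=int)
    face_map: dict[tuple[int, int, int], tuple[int, int]] = {}
    for t in range(T):
        quad = tets[t]
        for k in range(4):
            face = tuple(sorted(np.delete(quad, k)))
            other = face_map.pop(face, None)
            if other is None:
                face_map[face] = (t, k)
            else:
                ot, ok = other
                neighbors[t, k] = ot
                neighbors[ot, ok] = t
    return neighbors


def classify_interior(t: Tetrahedralization) -> np.ndarray:
    """Flag tetrahedra interior to the molecule: alpha complex at alpha = 0,
    i.e. ``sq_orthoradius <= 0`` (with a small positive roundoff band)."""
    t.interior = t.sq_orthoradius <= INTERIOR_TOL
    return t.interior
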